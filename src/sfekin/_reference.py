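"""Published regression equations, shipped for display and comparison only.

These are the response-surface equations as printed in the source study.
They are *not* used in any computation: all analyses in this package refit
the embedded design tables.  The printed equations cannot be reproduced
exactly from the printed (rounded) responses — and the uncoded quadratic
carries at least one typographical error (its T·G coefficient has the
opposite sign from the refit, and evaluating it at the reported optimum
does not return the reported prediction) — so the refit is authoritative.
"""

# Step I: 2^2 factorial, global extract yield (% w/w), coded P and modifier M.
PUBLISHED_FACTORIAL_YIELD = {
    "const": 1.81281,
    "P": 0.32906,
    "M": 0.29094,
    "P*M": 0.06094,
}
PUBLISHED_FACTORIAL_R2 = 0.9981

# Step II: full quadratic for p-anisic acid selectivity (% w/w), uncoded
# P (bar), T (degC), G (mesh).
PUBLISHED_SELECTIVITY_SURFACE = {
    "const": -9.742,
    "P": 8.782e-2,
    "T": 5.495e-2,
    "G": 1.660e-2,
    "P*P": -1.429e-4,
    "T*T": -1.631e-3,
    "G*G": -3.523e-5,
    "P*T": -1.003e-5,
    "P*G": -1.858e-4,
    "T*G": -7.097e-4,
}
PUBLISHED_SELECTIVITY_R2 = 0.9125

# Reported optimum of the selectivity surface and the triplicate validation.
PUBLISHED_OPTIMUM = {"P": 278.8, "T": 40.0, "G": 42.0}
PUBLISHED_OPTIMUM_PREDICTED = 2.76  # % w/w
PUBLISHED_OPTIMUM_MEASURED = 2.51  # % w/w, mean of triplicate at 279 bar
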