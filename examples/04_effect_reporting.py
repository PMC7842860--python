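"""Reporting conventions: odds ratios, zero-odds folds, percent changes.

Takes coefficients of the size reported in country-level mortality-rate
analyses and shows the three reporting transforms together with Wald
intervals on the transformed scale.
"""

import mtwopart as mt

# a strongly protective zero-part coefficient: each unit of the covariate
# multiplies the odds of a *positive* outcome by exp(1.417) — equivalently
# it reduces the odds of a zero outcome about 4-fold
coef, se = -1.417, 0.544
fold = mt.effect_transform(coef, "zero_odds_fold")
hi, lo = mt.wald_ci(coef, se, 0.95, "inv_exp")
print(f"zero part: coef {coef} -> odds of a zero reduced "
      f"{fold:.2f}-fold (95% CI {hi:.2f}-{lo:.2f})")

coef = 0.0736
print(f"zero part: coef {coef} -> OR {mt.effect_transform(coef, 'odds_ratio'):.3f} "
      "for a positive outcome per unit increase")

# a large negative continuous-part coefficient: the marginal mean drops by
# 1 - exp(coef), i.e. nearly everything
coef = -4.7273
print(f"continuous part: coef {coef} -> "
      f"{mt.effect_transform(coef, 'pct_change'):.2f}% reduction of the marginal mean")
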