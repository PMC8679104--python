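# One-way deterministic sensitivity catalogue.
#
# Each entry names a single perturbation; run_scenarios executes one full
# deterministic model run per endpoint and orients low/high totals.
# Kinds:
#   price_ci           - pooled price mean at the 2.5th/97.5th percentile of
#                        its gamma prior (category: promotion|hwf|soap|formative)
#   param_pair         - a CostParameters field at low/high values
#   price_usd_override - flat US$ per-household price in every country (one-sided)
#   flag               - a ScenarioSpec switch (one-sided)
#   price_scale        - every pooled mean multiplied by low/high factors
scenarios:
  - id: promotion_price_95ci
    parameter: promotion price (95% CI)
    kind: price_ci
    category: promotion
  - id: hwf_price_95ci
    parameter: handwashing facility price (95% CI)
    kind: price_ci
    category: hwf
  - id: soap_price_95ci
    parameter: soap price (95% CI)
    kind: price_ci
    category: soap
  - id: discount_rate
    parameter: discount_rate
    kind: param_pair
    low: 0.0
    high: 0.06
  - id: promotion_useful_life
    parameter: promo_life
    kind: param_pair
    low: 3
    high: 7
  - id: hwf_useful_life
    parameter: hwf_life
    kind: param_pair
    low: 3
    high: 7
  - id: topup_fraction
    parameter: topup_fraction
    kind: param_pair
    low: 0.125
    high: 0.5
  - id: hwf_homemade
    parameter: home-made handwashing facility
    kind: price_usd_override
    category: hwf
    usd: 1.2
  - id: economies_of_scale
    parameter: economies of scale
    kind: flag
    flag: economies_of_scale
  - id: alternative_promotion
    parameter: promotion excluding one-to-one activities
    kind: flag
    flag: promotion_mode_alternative
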