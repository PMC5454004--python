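"""Convert a classifier operating point into population-screening yield.

A screen with given sensitivity/specificity applied at the population
prevalence of the FX premutation in females (1 in 151) has a positive
predictive value far above the prevalence itself — the enrichment factor is
the fold-reduction in confirmatory genetic tests per true carrier found.
"""

import fxscreen as fx

prevalence = 1 / 151
print(f"population prevalence: {100 * prevalence:.3f}% (1/151)")

for sens, spec in ((0.81, 0.81), (0.90, 0.90), (1.00, 0.80)):
    est = fx.screening_ppv(sens, spec, prevalence)
    print(f"sens={sens:.2f} spec={spec:.2f} -> "
          f"PPV {est.ppv_percent:.2f}%  enrichment {est.enrichment:.1f}x")

# At sens=spec=0.81 the PPV is ~2.8% vs the 0.662% base rate: roughly a
# four-fold enrichment, i.e. four times fewer genetic tests per carrier
# identified than unscreened testing.
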