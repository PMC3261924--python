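# Default simulator configuration: ancestral regulatory system and per-step
# event probabilities.  The ancestor has 3 activating factors with distinct
# binding specificities and disjoint expression domains; the first 2 factors
# have one binding site each in the cis element.
alphabet_size: 12
domain_universe: 10
n_factors: 3
n_sites: 2
rates:
  site_gain: 0.05
  site_loss: 0.05
  trans_domain_change: 0.05
  coevolution_conserving: 0.03
  coevolution_diverging: 0.03
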