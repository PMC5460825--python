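# Default synthetic composition: 7298 binding sites whose per-class counts
# mirror the motif accounting of the hippocampal GR binding-site set
# (49.0% full GRE; 89.9% carrying some GRE form, i.e. 735 sites with
# neither form; 54.6% NF-1 half-sites; 17.1% bHLH; 126 nGRE-containing
# sites of which all but six co-occur with a GRE form).
#
# Class weights set the composition-dependent enrichment used by the read
# simulator: site weight = 1 + sum of planted class weights, so composite
# GRE+NF-1/bHLH sites are the strongest peaks and isolated half-sites the
# weakest.
n_sites: 7298
peak_halfwidth: 100
classes:
  full_gre: {count: 3576, offset_sd: 15.0, weight: 1.0}
  gre_half: {count: 2987, offset_sd: 25.0, weight: 0.4}
  nf1_half: {count: 3985, offset_sd: 60.0, weight: 0.6}
  bhlh:     {count: 1248, offset_sd: 60.0, weight: 0.6}
  ngre:     {count: 126,  offset_sd: 60.0, weight: 0.0}
ngre_with_gre: 120
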