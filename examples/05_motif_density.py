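"""GCCARG binding-site density in promoters of a gene set vs random sets.

Promoters are 1 kb of upstream sequence; the consensus site GCCARG is
scanned on both strands, overlaps included. Three planted sites per target
promoter sit on top of the uniform background (~0.97 sites/kb at GC 0.5),
and the permutation test against random same-size gene sets makes the
enrichment quantitative.
"""

import phregulon as pr
from phregulon.motif import MotifSpec, expected_uniform_density, scan_motif

promoters, membership, planted = pr.generate_promoter_set(
    400, length=1000, gc=0.5, planted={"pacc_up": (60, 3)}, seed=2
)

spec = MotifSpec()  # GCCARG, both strands, 1-kb window
example = next(iter(membership["pacc_up"]))
hits = scan_motif(promoters.sequences[example], spec)
print(f"promoter {example}: {len(hits)} sites at positions {[p for p, s in hits]}")

res = pr.motif_enrichment(promoters, membership["pacc_up"], spec, n_draws=999, seed=0)
print(f"\ntarget-set density     : {res.density:.2f} sites/kb over {res.total_kb:.0f} kb")
print(f"random-set background  : {res.background_mean:.2f} +- {res.background_sd:.2f} sites/kb")
print(f"closed-form uniform    : {expected_uniform_density():.2f} sites/kb")
print(f"permutation P          : {res.pvalue:.4f} ({len(res.background_densities)} draws)")
print("-> ~3 planted sites/kb above a ~1/kb background, the signature of a",
      "directly bound target set.")
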