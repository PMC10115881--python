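"""Structural target deconvolution of a hit peptide.

Scans the lead hit IPIQLKA against a synthetic interface fixture in which
one complex carries the DEEIERQLKALG segment (the C-terminal MIT-interacting
motif context of CHMP2B), ranks candidate complexes by mismatches and
disease-GO sharing, and proposes longer peptide variants from the source
chain.
"""

from pepscreen import gen_interface_fixture, propose_extensions
from pepscreen.target_deconvolution import deconvolve

peptide = "IPIQLKA"
fixture = gen_interface_fixture(8, planted=(peptide, "DEEIERQLKALG"), seed=42)

ranked = deconvolve(peptide, fixture, max_mismatch=3)
print(f"{len(ranked)} candidate complexes within 3 mismatches, ranked by "
      f"(mismatches, shared disease GO terms):")
for m in ranked:
    print(f"  rank {m.rank}: {m.complex_id}/{m.partner}  window={m.window} "
          f" mismatches={m.mismatches}  identity={m.identity:.2f} "
          f" pd_go={m.pd_go_count}")

best = ranked[0]
print(f"\nbest placement: {best.window} at chain position {best.offset} "
      f"({best.mismatches} mismatches — the motif the hit only partially copies)")
for L in (10, 12):
    variants = propose_extensions(best, [L], fixture)
    print(f"length-{L} variants containing the match window: {variants}")
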