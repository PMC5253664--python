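"""In-silico digestion, peptide masses, ppm matching and coverage.

Digests a toy sequence with trypsin + AspN (cut after K/R, before D),
computes monoisotopic peptide masses, matches a simulated precursor at
10 ppm, and reports sequence coverage -- the bookkeeping needed to map MS
species back to residues.
"""

from oxfoot.digestion import (
    ASPN, TRYPSIN, coverage, digest, match_mass, pepsin,
)

SEQ = "MKWVTFISLLFLFSSAYSRGVFRRDAHK"

peps = digest(SEQ, [TRYPSIN, ASPN], missed=1)
print(f"trypsin+AspN, <=1 missed cleavage: {len(peps)} peptides")
for p in peps[:6]:
    print(f"  {p.start:>3d}-{p.end:<3d} {p.sequence:<12s} {p.mass:10.5f} Da"
          f"  (missed={p.missed})")

observed = peps[0].mass * (1 + 4e-6)  # a precursor 4 ppm off
hits = match_mass(observed, peps, tol_ppm=10)
print(f"\nprecursor {observed:.5f} Da matches {len(hits)} peptide(s); "
      f"best: {hits[0][0].sequence} at {hits[0][1]:+.1f} ppm")

frac, _ = coverage(peps, len(SEQ))
pep_frac, _ = coverage(digest(SEQ, pepsin(min_length=5, max_length=30)), len(SEQ))
print(f"\ncoverage: trypsin+AspN {frac:.0%}, nonspecific pepsin {pep_frac:.0%}")
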