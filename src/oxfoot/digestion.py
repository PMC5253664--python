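"""In-silico proteolysis and peptide mass bookkeeping.

Covers the digestion rules used for footprinting sample prep: trypsin
cleaves after Lys/Arg, AspN before Asp (no proline exception), LysC after
Lys, and pepsin is modelled as nonspecific cleavage bounded by peptide
length. Peptide monoisotopic masses are the residue-mass sum plus water;
precursor matching uses a ppm tolerance (default 10 ppm). Coverage is the
union of peptide intervals over the sequence length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._tables import MONOISOTOPIC_MASS, WATER_MONOISOTOPIC

__all__ = [
    "EnzymeRule",
    "Peptide",
    "TRYPSIN",
    "ASPN",
    "LYSC",
    "pepsin",
    "digest",
    "monoisotopic_mass",
    "match_mass",
    "coverage",
]


class DigestionError(ValueError):
    pass


@dataclass(frozen=True)
class EnzymeRule:
    """A cleavage specification.

    Specific enzymes cut after any residue in ``after`` and before any in
    ``before``; a nonspecific enzyme instead enumerates every substring
    within [min_length, max_length].
    """

    name: str
    after: frozenset[str] = frozenset()
    before: frozenset[str] = frozenset()
    nonspecific: bool = False
    min_length: int = 1
    max_length: int = 50

    def __post_init__(self) -> None:
        if self.nonspecific:
            if not 1 <= self.min_length <= self.max_length:
                raise DigestionError("need 1 <= min_length <= max_length")
        elif not (self.after or self.before):
            raise DigestionError(f"{self.name}: specific rule with no cut residues")


TRYPSIN = EnzymeRule("trypsin", after=frozenset("KR"))
ASPN = EnzymeRule("aspn", before=frozenset("D"))
LYSC = EnzymeRule("lysc", after=frozenset("K"))


def pepsin(min_length: int = 5, max_length: int = 30) -> EnzymeRule:
    """Pepsin at low pH modelled as nonspecific cleavage with length bounds."""
    return EnzymeRule("pepsin", nonspecific=True,
                      min_length=min_length, max_length=max_length)


@dataclass(frozen=True)
class Peptide:
    """A digest product with 1-based inclusive coordinates on its parent."""

    start: int
    end: int
    sequence: str
    mass: float
    missed: int = 0
    chain: str = "A"

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise DigestionError("peptide interval does not match its sequence")


def monoisotopic_mass(sequence: str) -> float:
    """Peptide monoisotopic mass: residue masses plus one water."""
    if not sequence:
        raise DigestionError("empty sequence has no mass")
    try:
        return sum(MONOISOTOPIC_MASS[c] for c in sequence) + WATER_MONOISOTOPIC
    except KeyError as exc:
        raise DigestionError(f"unknown residue {exc.args[0]!r}") from None


def _cut_sites(sequence: str, rules: list[EnzymeRule]) -> list[int]:
    """Positions i meaning a cut between residue i and i+1 (1-based)."""
    after = frozenset().union(*(r.after for r in rules))
    before = frozenset().union(*(r.before for r in rules))
    sites = set()
    for i in range(1, len(sequence)):  # boundary after residue i
        if sequence[i - 1] in after or sequence[i] in before:
            sites.add(i)
    return sorted(sites)


def digest(
    sequence: str,
    rules: list[EnzymeRule] | EnzymeRule,
    missed: int = 0,
    chain: str = "A",
) -> list[Peptide]:
    """Enumerate digest peptides, sorted by (start, end).

    For specific enzymes the cut-site set is the union over all rules and
    peptides spanning up to ``missed`` skipped sites are included. A
    nonspecific rule (pepsin) yields every substring within its length
    bounds and must not be mixed with specific rules.
    """
    if isinstance(rules, EnzymeRule):
        rules = [rules]
    if not sequence:
        raise DigestionError("empty sequence")
    nonspec = [r for r in rules if r.nonspecific]
    if nonspec:
        if len(rules) > 1:
            raise DigestionError("nonspecific rule cannot be combined with others")
        rule = nonspec[0]
        peptides = [
            Peptide(
                start=i + 1, end=i + ln, sequence=sequence[i : i + ln],
                mass=monoisotopic_mass(sequence[i : i + ln]), chain=chain,
            )
            for ln in range(rule.min_length, min(rule.max_length, len(sequence)) + 1)
            for i in range(len(sequence) - ln + 1)
        ]
        return sorted(peptides, key=lambda p: (p.start, p.end))

    boundaries = [0, *_cut_sites(sequence, rules), len(sequence)]
    peptides = []
    for i in range(len(boundaries) - 1):
        for skip in range(missed + 1):
            j = i + 1 + skip
            if j >= len(boundaries):
                break
            start, end = boundaries[i] + 1, boundaries[j]
            seq = sequence[start - 1 : end]
            peptides.append(
                Peptide(start=start, end=end, sequence=seq,
                        mass=monoisotopic_mass(seq), missed=skip, chain=chain)
            )
    return sorted(peptides, key=lambda p: (p.start, p.end))


def match_mass(
    observed: float,
    theoretical: list[Peptide],
    tol_ppm: float = 10.0,
) -> list[tuple[Peptide, float]]:
    """Peptides whose mass matches ``observed`` within ``tol_ppm``.

    Returns (peptide, ppm error) pairs sorted by absolute ppm error;
    isobaric peptides are all returned.
    """
    if not tol_ppm > 0:
        raise DigestionError("tol_ppm must be positive")
    hits = []
    for pep in theoretical:
        ppm = (observed - pep.mass) / pep.mass * 1e6
        if abs(ppm) <= tol_ppm:
            hits.append((pep, ppm))
    return sorted(hits, key=lambda h: abs(h[1]))


def coverage(
    peptides: list[Peptide],
    sequence_length: int,
) -> tuple[float, list[tuple[int, int]]]:
    """Fraction of the sequence covered and the merged covered intervals."""
    if not peptides:
        return 0.0, []
    for p in peptides:
        if p.start < 1 or p.end > sequence_length:
            raise DigestionError(
                f"peptide {p.start}-{p.end} outside 1-{sequence_length}"
            )
    intervals = sorted((p.start, p.end) for p in peptides)
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    covered = sum(e - s + 1 for s, e in merged)
    return covered / sequence_length, merged
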