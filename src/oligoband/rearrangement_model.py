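"""Karyotype and rearrangement modelling at probe (band) granularity.

Breakpoints live in the gaps between bands: gap index k on a chromosome of
n bands means "between band k and band k+1" (0 = before the first band,
n = after the last).  Banding cannot resolve within-band breaks, so
sub-band breakpoints are out of model.  The 2:2 meiotic segregation of a
reciprocal-translocation quadrivalent is enumerated exhaustively (alternate,
adjacent-I, adjacent-II); 3:1 and 4:0 segregations are not modelled.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .colour_scheme import ColourToken, Scheme
from .errors import RearrangementError

#: Expected chromosome count of a normal diploid pig cell.
NORMAL_CHROMOSOME_COUNT = 38


@dataclass(frozen=True)
class BandRef:
    """One band with its provenance: originating chromosome and rank there."""

    donor: str
    rank: int  # 1-based rank on the donor chromosome
    token: ColourToken


@dataclass
class ChromosomeCopy:
    """One physical chromosome copy (possibly derivative)."""

    name: str  # e.g. "SSC3" or "der3"
    homolog_index: int
    bands: list  # of BandRef

    def tokens(self) -> list:
        return [b.token for b in self.bands]

    @property
    def is_derivative(self) -> bool:
        return len({b.donor for b in self.bands}) > 1 or self.name.startswith("der")


@dataclass
class Karyotype:
    copies: list = field(default_factory=list)
    ploidy_note: str = "2n"

    def count(self) -> int:
        return len(self.copies)

    def find(self, name: str, homolog_index: int | None = None) -> list:
        return [
            c
            for c in self.copies
            if c.name == name and (homolog_index is None or c.homolog_index == homolog_index)
        ]


@dataclass(frozen=True)
class Rearrangement:
    """A structural rearrangement described by donors and band-gap indices."""

    type: str  # "rcp" | "t_nonreciprocal" | "add"
    donors: tuple
    breakpoints: tuple  # gap index per donor
    inserted_material: tuple = ()  # ColourTokens, for add
    donor_side: str = "q"  # for t_nonreciprocal: which donor end moves

    def __post_init__(self):
        if self.type not in ("rcp", "t_nonreciprocal", "add"):
            raise RearrangementError(f"unknown rearrangement type {self.type!r}")
        if self.type == "rcp" and len(self.donors) != 2:
            raise RearrangementError("rcp requires exactly two donors")
        if self.type == "add" and (len(self.donors) != 1 or not self.inserted_material):
            raise RearrangementError("add requires one donor and inserted tokens")


def karyotype_from_scheme(scheme: Scheme, sex: tuple = ("SSCX", "SSCY")) -> Karyotype:
    """Diploid karyotype: two homologs per autosome, one per sex chromosome."""
    copies = []
    for chrom, pat in scheme.patterns.items():
        bands = [BandRef(chrom, i + 1, tok) for i, tok in enumerate(pat.tokens)]
        n_copies = 1 if chrom in sex else 2
        for h in range(n_copies):
            copies.append(ChromosomeCopy(chrom, h, list(bands)))
    return Karyotype(copies=copies)


def _check_gap(gap: int, n: int, chrom: str) -> None:
    if not (0 <= gap <= n):
        raise RearrangementError(f"gap {gap} out of range 0..{n} on {chrom}")


def build_quadrivalent(
    chrom_a: str,
    tokens_a: Sequence[ColourToken],
    chrom_b: str,
    tokens_b: Sequence[ColourToken],
    gap_a: int,
    gap_b: int,
) -> dict:
    """The four quadrivalent members of an rcp as band-reference lists."""
    _check_gap(gap_a, len(tokens_a), chrom_a)
    _check_gap(gap_b, len(tokens_b), chrom_b)
    a = [BandRef(chrom_a, i + 1, t) for i, t in enumerate(tokens_a)]
    b = [BandRef(chrom_b, i + 1, t) for i, t in enumerate(tokens_b)]
    return {
        "A": a,
        "B": b,
        "derA": a[:gap_a] + b[gap_b:],
        "derB": b[:gap_b] + a[gap_a:],
    }


def apply_rearrangement(karyotype: Karyotype, r: Rearrangement, scheme: Scheme) -> Karyotype:
    """Return a new karyotype with one homolog per donor replaced.

    rcp: the two donors exchange distal (q-side) segments at their gap
    indices.  t_nonreciprocal: the first donor's terminal segment (p or q
    side per ``donor_side``) moves to the second donor's q terminus; nothing
    moves back.  add: the inserted tokens are placed at the stated gap on
    one homolog of the single donor.
    """
    copies = [ChromosomeCopy(c.name, c.homolog_index, list(c.bands)) for c in karyotype.copies]

    def _take(name):
        for c in copies:
            if c.name == name and not c.is_derivative:
                return c
        raise RearrangementError(f"donor {name!r} not present in karyotype")

    if r.type == "rcp":
        da, db = r.donors
        ca, cb = _take(da), _take(db)
        quad = build_quadrivalent(
            da, ca.tokens(), db, cb.tokens(), r.breakpoints[0], r.breakpoints[1]
        )
        ca.bands, ca.name = quad["derA"], f"der{_short(da)}"
        cb.bands, cb.name = quad["derB"], f"der{_short(db)}"
    elif r.type == "t_nonreciprocal":
        donor, acceptor = r.donors
        cd, cacc = _take(donor), _take(acceptor)
        gap = r.breakpoints[0]
        _check_gap(gap, len(cd.bands), donor)
        if r.donor_side == "q":
            moved, kept = cd.bands[gap:], cd.bands[:gap]
        else:
            # a p-terminal fragment joins the acceptor q terminus by its
            # broken (proximal) end, so its band order reverses
            moved, kept = cd.bands[:gap][::-1], cd.bands[gap:]
        cd.bands, cd.name = kept, f"der{_short(donor)}"
        cacc.bands, cacc.name = cacc.bands + moved, f"der{_short(acceptor)}"
    elif r.type == "add":
        (donor,) = r.donors
        c = _take(donor)
        gap = r.breakpoints[0]
        _check_gap(gap, len(c.bands), donor)
        inserted = [BandRef("?", 0, t) for t in r.inserted_material]
        c.bands = c.bands[:gap] + inserted + c.bands[gap:]
        c.name = f"der{_short(donor)}"
    return Karyotype(copies=copies, ploidy_note=karyotype.ploidy_note)


def _short(chrom: str) -> str:
    return chrom[3:] if chrom.startswith("SSC") else chrom


def derivative_signature(copy_or_bands) -> list:
    """Ordered colour tokens of a (derivative) chromosome copy."""
    bands = copy_or_bands.bands if isinstance(copy_or_bands, ChromosomeCopy) else copy_or_bands
    return [b.token for b in bands]


# ---------------------------------------------------------------------------
# meiotic 2:2 segregation


@dataclass
class GameteClass:
    label: str
    chromosomes: tuple  # 2 of {"A", "B", "derA", "derB"}
    balanced: bool
    expected_signals: Counter  # multiset of (donor, rank, token)


_CLASS_LABELS = {
    frozenset({"A", "B"}): "alternate_normal",
    frozenset({"derA", "derB"}): "alternate_translocated",
    frozenset({"A", "derB"}): "adjacent_I_a",
    frozenset({"derA", "B"}): "adjacent_I_b",
    frozenset({"A", "derA"}): "adjacent_II_a",
    frozenset({"B", "derB"}): "adjacent_II_b",
}


def _signals(bands: Iterable[BandRef]) -> Counter:
    return Counter((b.donor, b.rank, b.token) for b in bands)


def enumerate_2_2_segregation(
    tokens_a: Sequence[ColourToken],
    tokens_b: Sequence[ColourToken],
    r: Rearrangement,
    chrom_a: str | None = None,
    chrom_b: str | None = None,
) -> list:
    """All six 2:2 gamete classes of an rcp quadrivalent.

    {A,B} and {derA,derB} segregate alternately and are balanced; {A,derB}
    and {derA,B} are adjacent-I; {A,derA} and {B,derB} adjacent-II.  A class
    is balanced iff its signal multiset equals the full haploid band multiset
    of the two donor chromosomes.
    """
    if r.type != "rcp":
        raise RearrangementError("2:2 segregation enumeration requires a reciprocal translocation")
    chrom_a = chrom_a or r.donors[0]
    chrom_b = chrom_b or r.donors[1]
    quad = build_quadrivalent(chrom_a, tokens_a, chrom_b, tokens_b, *r.breakpoints)
    full = _signals(quad["A"]) + _signals(quad["B"])
    classes = []
    for members, label in _CLASS_LABELS.items():
        m1, m2 = sorted(members)
        signals = _signals(quad[m1]) + _signals(quad[m2])
        classes.append(
            GameteClass(
                label=label,
                chromosomes=(m1, m2),
                balanced=signals == full,
                expected_signals=signals,
            )
        )
    order = [
        "alternate_normal",
        "alternate_translocated",
        "adjacent_I_a",
        "adjacent_I_b",
        "adjacent_II_a",
        "adjacent_II_b",
    ]
    classes.sort(key=lambda c: order.index(c.label))
    return classes


def multiset_distance(a: Counter, b: Counter) -> int:
    """Size of the symmetric multiset difference."""
    keys = set(a) | set(b)
    return sum(abs(a.get(k, 0) - b.get(k, 0)) for k in keys)


def classify_sperm_signals(
    observed: Counter | Iterable,
    classes: Sequence[GameteClass],
    tolerance: int = 0,
) -> dict:
    """Assign an observed per-head signal multiset to the nearest gamete class.

    Classes whose expected multisets coincide (the two balanced alternate
    classes at probe granularity) are merged and reported as ``balanced``.
    Result: {label, distance, flagged, ambiguous}; ``ambiguous`` when two
    distinct multisets tie for nearest or the best distance exceeds
    ``tolerance``; ``flagged`` when the match is inexact (e.g. a
    decondensation duplication artifact absorbed by the tolerance).
    """
    obs = observed if isinstance(observed, Counter) else Counter(observed)
    # merge classes with identical expected multisets
    merged: list = []
    for gc in classes:
        for group in merged:
            if group[0].expected_signals == gc.expected_signals:
                group.append(gc)
                break
        else:
            merged.append([gc])

    scored = []
    for group in merged:
        dist = multiset_distance(obs, group[0].expected_signals)
        if len(group) > 1 and all(g.balanced for g in group):
            label = "balanced"
        else:
            label = group[0].label
        scored.append((dist, label))
    scored.sort()
    best_dist, best_label = scored[0]
    tied = sum(1 for d, _ in scored if d == best_dist) > 1
    ambiguous = tied or best_dist > tolerance
    return {
        "label": "ambiguous" if ambiguous else best_label,
        "nearest": best_label,
        "distance": best_dist,
        "flagged": best_dist > 0,
        "ambiguous": ambiguous,
    }
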