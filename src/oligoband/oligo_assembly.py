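"""Candidate 39mer filtering, orthogonal 20mer selection and oligo assembly.

The synthesis-ready oligo concatenates a genome-homologous 39mer with
orthogonal 20mer segments: a region complementary to a chromosome-specific
reverse primer, (optionally) a region complementary to a shared forward
primer, and a fluorophore-specific handle to which a dye-labelled detection
oligo hybridizes.  Orthogonal 20mers are screened for self- and
hetero-dimerization free energy (nearest-neighbour model, 37 degC) against a
-9 kcal/mol threshold and attributed to primer or handle roles by GC clamp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils import MeltingTemp

from .errors import LayoutError, SelectionError, SequenceError
from .panel_design import OLIGO_LEN, CandidateOligo, Probe

T7_PROMOTER = "TAATACGACTCACTATAG"

_COMP = str.maketrans("ACGT", "TGCA")

# SantaLucia (1998) unified nearest-neighbour free energies at 37 degC,
# kcal/mol per dinucleotide stack (5'->3' top strand, Watson-Crick duplex).
NN_DELTA_G37 = {
    "AA": -1.00, "TT": -1.00,
    "AT": -0.88,
    "TA": -0.58,
    "CA": -1.45, "TG": -1.45,
    "GT": -1.44, "AC": -1.44,
    "CT": -1.28, "AG": -1.28,
    "GA": -1.30, "TC": -1.30,
    "CG": -2.17,
    "GC": -2.24,
    "GG": -1.84, "CC": -1.84,
}
# duplex initiation terms per terminal base pair
_INIT_GC = 0.98
_INIT_AT = 1.03

DEFAULT_DIMER_THRESHOLD = -9.0


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _check_acgt(seq: str) -> None:
    if not seq or set(seq) - set("ACGT"):
        raise SequenceError(f"sequence contains non-ACGT characters: {seq!r}")


# ---------------------------------------------------------------------------
# 39mer mining (simplified balance-mode stand-in)


@dataclass(frozen=True)
class FilterParams:
    """Predicates for candidate 39mer mining.

    The uniqueness screen counts canonical k-mers genome-wide in a hash
    table; a 39mer is kept only if each of its constituent k-mers occurs at
    most ``kmer_max_count`` times.  This replaces an aligner-based
    off-target check.
    """

    tm_min: float = 60.0
    tm_max: float = 85.0
    gc_min: float = 0.25
    gc_max: float = 0.75
    homopolymer_max: int = 6
    k: int = 18
    kmer_max_count: int = 1


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _canonical_kmers(seq: str, k: int):
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        rc = revcomp(km)
        yield km if km <= rc else rc


def filter_39mers(sequences: Mapping[str, str], params: FilterParams = FilterParams()):
    """Scan soft-masked chromosome sequences for candidate 39mers.

    ``sequences`` maps chromosome id to sequence; lowercase bases count as
    masked and any window touching one is skipped, as are windows with N.
    Remaining windows must pass GC, nearest-neighbour Tm, homopolymer and
    genome-wide k-mer-uniqueness predicates.  Output order follows the
    genomic scan and is independent of the mapping's key order.
    """
    if not sequences or all(len(s) == 0 for s in sequences.values()):
        raise SequenceError("empty FASTA: no sequence to mine")
    if params.tm_min > params.tm_max or params.gc_min > params.gc_max:
        raise SequenceError("inverted filter window bounds")

    counts: dict = {}
    for seq in sequences.values():
        upper = seq.upper()
        for i in range(len(upper) - params.k + 1):
            km = upper[i : i + params.k]
            if set(km) - set("ACGT"):
                continue
            rc = revcomp(km)
            canon = km if km <= rc else rc
            counts[canon] = counts.get(canon, 0) + 1

    out = []
    for chrom in sorted(sequences):
        seq = sequences[chrom]
        for i in range(len(seq) - OLIGO_LEN + 1):
            window = seq[i : i + OLIGO_LEN]
            if not window.isupper() or set(window) - set("ACGT"):
                continue
            gc = (window.count("G") + window.count("C")) / OLIGO_LEN
            if not (params.gc_min <= gc <= params.gc_max):
                continue
            if _max_homopolymer(window) > params.homopolymer_max:
                continue
            tm = MeltingTemp.Tm_NN(window)
            if not (params.tm_min <= tm <= params.tm_max):
                continue
            if any(counts[k] > params.kmer_max_count for k in _canonical_kmers(window, params.k)):
                continue
            out.append(CandidateOligo(chrom, i, i + OLIGO_LEN, window))
    return out


def load_fasta(path) -> dict:
    """Plain FASTA reader preserving case (soft-masking)."""
    seqs: dict = {}
    name = None
    chunks: list = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


# ---------------------------------------------------------------------------
# dimer thermodynamics


def _run_delta_g(seq: str) -> float:
    """Free energy of a fully paired contiguous duplex given the top strand."""
    dg = sum(NN_DELTA_G37[seq[i : i + 2]] for i in range(len(seq) - 1))
    for base in (seq[0], seq[-1]):
        dg += _INIT_GC if base in "GC" else _INIT_AT
    return dg


def dimer_free_energy(a: str, b: str) -> float:
    """Most stable hybridization ΔG (kcal/mol, 37 degC) between two oligos.

    All ungapped antiparallel alignments of ``a`` against ``b`` are
    enumerated; within each alignment every maximal run of ≥ 2 consecutive
    Watson-Crick pairs is scored with the unified nearest-neighbour stack
    table plus duplex-initiation terms, and the minimum (most negative) run
    energy over all alignments is returned.  With no pairing possible the
    result is 0.  More negative means a stronger dimer; self-dimers are
    obtained with ``a == b``.
    """
    _check_acgt(a)
    _check_acgt(b)
    if len(a) < 2 or len(b) < 2:
        raise SequenceError("dimer_free_energy requires sequences of length >= 2")
    br = b[::-1]
    comp_a = a.translate(_COMP)
    best = 0.0
    for shift in range(-(len(b) - 1), len(a)):
        lo = max(0, shift)
        hi = min(len(a), len(br) + shift)
        run_start = None
        i = lo
        while i <= hi:
            paired = i < hi and comp_a[i] == br[i - shift]
            if paired and run_start is None:
                run_start = i
            elif not paired and run_start is not None:
                if i - run_start >= 2:
                    best = min(best, _run_delta_g(a[run_start:i]))
                run_start = None
            i += 1
    return best


# ---------------------------------------------------------------------------
# orthogonal set selection


@dataclass
class OrthogonalSet:
    """Mutually compatible 20mer sequences attributed to functional roles."""

    forward: str
    reverse_primers: dict  # chrom_id -> 20mer
    handles: dict  # fluorophore -> 20mer
    threshold: float = DEFAULT_DIMER_THRESHOLD

    @property
    def detection_oligos(self) -> dict:
        """fluorophore -> (sequence hybridizing to the handle, dye label)."""
        from .colour_scheme import FLUOROPHORE_LABELS

        return {
            fl: (revcomp(seq), FLUOROPHORE_LABELS.get(fl, fl))
            for fl, seq in self.handles.items()
        }

    def members(self) -> list:
        return [self.forward, *self.reverse_primers.values(), *self.handles.values()]


def _has_gc_clamp(seq: str) -> bool:
    return set(seq[-2:]) <= set("GC")


def select_orthogonal_set(
    candidates: Sequence[str],
    chrom_ids: Sequence[str],
    fluorophores: Sequence[str] = ("FAM", "A550", "A647"),
    delta_g_threshold: float = DEFAULT_DIMER_THRESHOLD,
    genome_kmers: set | None = None,
    screen_k: int = 15,
    exact: bool = False,
) -> OrthogonalSet:
    """Pick a compatible 20mer set and attribute roles.

    Compatibility: every retained sequence passes the self-dimer threshold
    and every retained pair passes the hetero-dimer threshold.  Selection is
    greedy in input order (deterministic); ``exact=True`` solves a maximum
    clique on the compatibility graph instead (candidate sets <= 30 only).
    When ``genome_kmers`` (a set of canonical k-mers of length ``screen_k``)
    is given, candidates sharing any k-mer with the genome are rejected —
    the stand-in for an alignment-based orthogonality screen.

    Roles: 3'-GC-clamped sequences are preferred for the forward and
    reverse primers, the remainder become fluorophore handles.
    """
    n_needed = 1 + len(chrom_ids) + len(fluorophores)
    usable = []
    for seq in candidates:
        _check_acgt(seq)
        if len(seq) != 20:
            raise SequenceError(f"orthogonal candidates must be 20mers, got {len(seq)} nt")
        if genome_kmers is not None:
            hit = any(
                (km if km <= revcomp(km) else revcomp(km)) in genome_kmers
                for km in (seq[i : i + screen_k] for i in range(len(seq) - screen_k + 1))
            )
            if hit:
                continue
        if dimer_free_energy(seq, seq) >= delta_g_threshold:
            usable.append(seq)

    if exact:
        if len(usable) > 30:
            raise SelectionError("exact selection limited to candidate sets <= 30")
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(len(usable)))
        for i in range(len(usable)):
            for j in range(i + 1, len(usable)):
                if dimer_free_energy(usable[i], usable[j]) >= delta_g_threshold:
                    g.add_edge(i, j)
        clique, _ = nx.algorithms.clique.max_weight_clique(g, weight=None)
        kept = [usable[i] for i in sorted(clique)]
    else:
        kept = []
        for seq in usable:
            if all(
                dimer_free_energy(seq, other) >= delta_g_threshold for other in kept
            ):
                kept.append(seq)
            if len(kept) >= n_needed:
                break

    if len(kept) < n_needed:
        raise SelectionError(
            f"only {len(kept)} compatible 20mers found, {n_needed} needed"
        )

    clamped = [s for s in kept if _has_gc_clamp(s)]
    unclamped = [s for s in kept if not _has_gc_clamp(s)]
    # primers drawn from GC-clamped pool first, handles from the rest
    primer_pool = clamped + unclamped
    forward = primer_pool.pop(0)
    reverse_primers = {c: primer_pool.pop(0) for c in chrom_ids}
    handle_pool = [s for s in kept if s != forward and s not in reverse_primers.values()]
    handle_pool.sort(key=_has_gc_clamp)  # unclamped first
    handles = {fl: handle_pool[i] for i, fl in enumerate(fluorophores)}
    return OrthogonalSet(forward, reverse_primers, handles, delta_g_threshold)


# ---------------------------------------------------------------------------
# oligo layouts and assembly


@dataclass(frozen=True)
class OligoLayout:
    """Ordered (role, length) segments of the synthesis-ready oligo."""

    name: str
    segments: tuple  # of (role, length_nt)
    declared_total_nt: int

    def total_nt(self) -> int:
        return sum(n for _, n in self.segments)

    def validate(self) -> list:
        """Report (not fix) discrepancies between segments and declared total."""
        issues = []
        if self.total_nt() != self.declared_total_nt:
            issues.append(
                f"layout {self.name}: segment lengths sum to {self.total_nt()} nt "
                f"but declared total is {self.declared_total_nt} nt"
            )
        homology = [n for r, n in self.segments if r == "homology"]
        if homology != [OLIGO_LEN]:
            issues.append(f"layout {self.name}: homology segment must be one {OLIGO_LEN}mer")
        return issues

    def offset_of(self, role: str) -> int:
        off = 0
        for r, n in self.segments:
            if r == role:
                return off
            off += n
        raise LayoutError(f"layout {self.name} has no segment {role!r}")


#: Four-segment layout: reverse-primer binding, homology, forward-primer
#: binding, detection handle (sums to 99 nt).
LAYOUT_FIG1 = OligoLayout(
    "fig1",
    (("reverse_binding", 20), ("homology", 39), ("forward_binding", 20), ("detection_handle", 20)),
    99,
)

#: Three-segment 79 nt layout matching the synthesized oligo length; the
#: forward-binding segment is the one omitted.
LAYOUT_79NT = OligoLayout(
    "79nt",
    (("reverse_binding", 20), ("homology", 39), ("detection_handle", 20)),
    79,
)

LAYOUTS = {"fig1": LAYOUT_FIG1, "79nt": LAYOUT_79NT}


@dataclass
class AssembledOligo:
    probe_id: str
    chrom_id: str
    final_sequence: str
    segments: tuple  # ordered (role, subsequence)
    start_bp: int = 0
    end_bp: int = 0
    fluorophore: str = ""

    def segment(self, role: str) -> str:
        for r, s in self.segments:
            if r == role:
                return s
        raise LayoutError(f"no segment {role!r}")


def assemble_oligo(
    candidate: CandidateOligo,
    layout: OligoLayout,
    oset: OrthogonalSet,
    probe: Probe,
    fluorophore: str | None = None,
) -> AssembledOligo:
    """Concatenate layout segments into the synthesis-ready sequence.

    The reverse-binding segment is the reverse complement of the
    chromosome-specific reverse primer, the forward-binding segment (when the
    layout has one) the reverse complement of the shared forward primer, and
    the handle is the fluorophore-specific handle sequence.  For paired-colour
    probes the caller passes the fluorophore chosen by the alternation rule;
    single-colour probes default to their token's only fluorophore.
    """
    if candidate.sequence is None:
        raise SequenceError(f"candidate at {candidate.chrom_id}:{candidate.start_bp} has no sequence")
    if fluorophore is None:
        if probe.colour is None or probe.colour.is_paired:
            raise LayoutError("fluorophore must be given for paired-colour probes")
        (fluorophore,) = probe.colour.fluorophores

    parts = []
    for role, length in layout.segments:
        if role == "reverse_binding":
            seq = revcomp(oset.reverse_primers[candidate.chrom_id])
        elif role == "homology":
            seq = candidate.sequence
        elif role == "forward_binding":
            seq = revcomp(oset.forward)
        elif role == "detection_handle":
            seq = oset.handles[fluorophore]
        else:
            raise LayoutError(f"unknown segment role {role!r}")
        if len(seq) != length:
            raise LayoutError(
                f"segment {role}: sequence length {len(seq)} != layout length {length}"
            )
        parts.append((role, seq))
    final = "".join(s for _, s in parts)
    return AssembledOligo(
        probe_id=probe.probe_id,
        chrom_id=candidate.chrom_id,
        final_sequence=final,
        segments=tuple(parts),
        start_bp=candidate.start_bp,
        end_bp=candidate.end_bp,
        fluorophore=fluorophore,
    )


def recover_homology(oligo: AssembledOligo, layout: OligoLayout) -> str:
    """Simulated priming: cut the 39mer back out at the layout offset."""
    off = layout.offset_of("homology")
    return oligo.final_sequence[off : off + OLIGO_LEN]


# ---------------------------------------------------------------------------
# order sheets


def emit_order_sheets(
    oligos: Iterable[AssembledOligo], oset: OrthogonalSet, outdir
) -> dict:
    """Write the oligo library and the primer/detection-oligo sheets as TSV.

    Reverse primers are exported with the T7 promoter prepended, detection
    oligos with their 3' dye annotation.
    Returns {"library": path, "primers": path}.
    """
    oligos = list(oligos)
    if not oligos:
        raise SequenceError("no oligos to export")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    lib = pd.DataFrame(
        {
            "chrom": [o.chrom_id for o in oligos],
            "probe": [o.probe_id for o in oligos],
            "fluorophore": [o.fluorophore for o in oligos],
            "homology_39mer": [o.segment("homology") for o in oligos],
            "start": [o.start_bp for o in oligos],
            "end": [o.end_bp for o in oligos],
            "final_sequence": [o.final_sequence for o in oligos],
        }
    )
    lib_path = outdir / "oligo_library.tsv"
    lib.to_csv(lib_path, sep="\t", index=False)

    rows = [("forward_primer", "FWD", oset.forward, "")]
    for chrom, seq in oset.reverse_primers.items():
        rows.append(("reverse_primer_T7", f"REV_{chrom}", T7_PROMOTER + seq, ""))
    for fl, (seq, dye) in oset.detection_oligos.items():
        rows.append(("detection_oligo", f"DET_{fl}", seq, f"3'-{dye}"))
    primers = pd.DataFrame(rows, columns=["role", "name", "sequence", "modification"])
    primers_path = outdir / "primers_detection.tsv"
    primers.to_csv(primers_path, sep="\t", index=False)
    return {"library": lib_path, "primers": primers_path}


def read_order_sheet(path, layout: OligoLayout) -> list:
    """Re-import an oligo library TSV into AssembledOligo records."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples(index=False):
        final = str(r.final_sequence)
        parts = []
        off = 0
        for role, length in layout.segments:
            parts.append((role, final[off : off + length]))
            off += length
        out.append(
            AssembledOligo(
                probe_id=str(r.probe),
                chrom_id=str(r.chrom),
                final_sequence=final,
                segments=tuple(parts),
                start_bp=int(r.start),
                end_bp=int(r.end),
                fluorophore=str(r.fluorophore),
            )
        )
    return out
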