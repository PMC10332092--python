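"""Probe panel design from candidate 39mer coordinates.

A probe is a genomic window covering a run of consecutive candidate 39mers
(3000 by default).  Windows are placed per chromosome under three rules:
a minimum resolvable gap between neighbouring probes, a margin from both
chromosome termini, and — among feasible placements — the smallest genomic
span (highest oligo density).  Placement uses equal genomic quantile anchors
with a densest-feasible-run snap; the quantile heuristic is our choice, the
constraints are the method's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .colour_scheme import ColourToken
from .errors import (
    CoordinateError,
    InfeasibleDesignError,
    PanelError,
    UnknownChromosomeError,
    WindowSizeError,
)

OLIGO_LEN = 39

#: Default minimum gap between neighbouring probes (bp).  Two probes closer
#: than roughly 7-8 Mb cannot be resolved as separate bands on a metaphase
#: chromosome, so 8 Mb is the conservative default.
DEFAULT_MIN_GAP_BP = 8_000_000

#: Default margin of terminal probes from the chromosome ends (bp).
DEFAULT_TERMINI_MARGIN_BP = 6_000_000


@dataclass(frozen=True)
class GenomeBuild:
    """Named assembly: ordered (chromosome id, length in bp) pairs."""

    name: str
    chromosomes: tuple

    def __post_init__(self):
        ids = [c for c, _ in self.chromosomes]
        if len(set(ids)) != len(ids):
            raise PanelError("duplicate chromosome ids in genome build")
        for c, ln in self.chromosomes:
            if ln <= 0:
                raise PanelError(f"non-positive length for chromosome {c}")

    @property
    def lengths(self) -> dict:
        return dict(self.chromosomes)

    def __contains__(self, chrom_id: str) -> bool:
        return chrom_id in self.lengths

    @classmethod
    def from_chrom_sizes(cls, path, name: str = "genome") -> "GenomeBuild":
        """Read a two-column (chrom, length) TSV, .fai-style."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        return cls(name, tuple((str(r[0]), int(r[1])) for r in df.itertuples(index=False)))


@dataclass(frozen=True)
class CandidateOligo:
    """One candidate 39mer: 0-based half-open genomic interval."""

    chrom_id: str
    start_bp: int
    end_bp: int
    sequence: str | None = None


@dataclass
class Probe:
    """A designed probe: the genomic span of its oligo run plus metadata."""

    probe_id: str
    chrom_id: str
    start_bp: int
    end_bp: int
    oligo_count: int
    colour: ColourToken | None = None
    rank_on_chrom: int = 0
    oligo_starts: np.ndarray | None = None

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def density_oligo_per_kb(self) -> float:
        return self.oligo_count / (self.span_bp / 1000.0)

    @property
    def midpoint_bp(self) -> float:
        return 0.5 * (self.start_bp + self.end_bp)


@dataclass
class ChromosomePanel:
    """Ordered probes of one chromosome."""

    chrom_id: str
    probes: list
    chrom_length_bp: int
    centromere_bp: int | None = None

    def __len__(self):
        return len(self.probes)


@dataclass
class PanelRow:
    """Per-chromosome summary statistics (one Table-style row)."""

    chrom_id: str
    n_probes: int
    mean_density: float
    mean_coverage_kb: float
    mean_interprobe_mb: float
    mean_dist_from_ends_mb: float


@dataclass
class PanelSummary:
    rows: list = field(default_factory=list)
    overall: dict = field(default_factory=dict)
    overall_sd: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([r.__dict__ for r in self.rows])
        total = {
            "chrom_id": "Total",
            "n_probes": self.overall["n_probes"],
            "mean_density": self.overall["mean_density"],
            "mean_coverage_kb": self.overall["mean_coverage_kb"],
            "mean_interprobe_mb": self.overall["mean_interprobe_mb"],
            "mean_dist_from_ends_mb": self.overall["mean_dist_from_ends_mb"],
        }
        return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


# ---------------------------------------------------------------------------
# candidate loading


def _looks_like_sequence(s: str, length: int) -> bool:
    return isinstance(s, str) and len(s) == length and set(s.upper()) <= set("ACGT")


def load_candidates(path, genome: GenomeBuild) -> dict:
    """Load candidate oligos from BED or headered TSV.

    Returns a mapping chrom_id -> DataFrame(start, end, sequence) sorted by
    start and deduplicated on (chrom, start).  BED name columns that look
    like a nucleotide sequence of the interval length are kept as sequences.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    has_header = "start" in first.lower().split("\t")[1:2] or first.lower().startswith(
        ("chrom\t", "chrom_id\t", "#chrom\t")
    )
    if has_header:
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lstrip("#").lower() for c in df.columns]
        df = df.rename(columns={"chrom_id": "chrom", "start_bp": "start", "end_bp": "end"})
    else:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
        df.columns = names
    if "sequence" not in df.columns:
        if "name" in df.columns:
            df["sequence"] = [
                n if _looks_like_sequence(n, e - s) else None
                for n, s, e in zip(df["name"], df["start"], df["end"])
            ]
        else:
            df["sequence"] = None

    lengths = genome.lengths
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        chrom = str(chrom)
        if chrom not in lengths:
            raise UnknownChromosomeError(f"chromosome {chrom!r} not in genome build")
        bad = sub[(sub["start"] < 0) | (sub["end"] > lengths[chrom])]
        if len(bad):
            rec = bad.iloc[0]
            raise CoordinateError(
                f"record {chrom}:{int(rec['start'])}-{int(rec['end'])} outside "
                f"chromosome of length {lengths[chrom]}"
            )
        sub = (
            sub[["start", "end", "sequence"]]
            .astype({"start": np.int64, "end": np.int64})
            .drop_duplicates(subset="start")
            .sort_values("start")
            .reset_index(drop=True)
        )
        out[chrom] = sub
    return out


# ---------------------------------------------------------------------------
# window selection


def _window_spans(starts: np.ndarray, n_oligo: int) -> np.ndarray:
    """Span of every run of n_oligo consecutive candidates (vectorised)."""
    return starts[n_oligo - 1 :] + OLIGO_LEN - starts[: len(starts) - n_oligo + 1]


def select_probe_windows(
    candidates,
    chrom_id: str,
    chrom_length_bp: int,
    n_probes: int,
    n_oligo: int = 3000,
    min_resolvable_bp: int = DEFAULT_MIN_GAP_BP,
    termini_margin_bp: int = DEFAULT_TERMINI_MARGIN_BP,
) -> ChromosomePanel:
    """Place ``n_probes`` windows of ``n_oligo`` consecutive candidates.

    Heuristic: the allowed interior (margins removed) is split into
    ``n_probes`` equal genomic quantile bins; within each bin the feasible
    run (satisfying the gap to the previously placed window and the termini
    margins) of smallest genomic span is chosen, earliest run on ties.

    Raises :class:`InfeasibleDesignError` naming the violated constraint
    when no placement exists.
    """
    if n_probes == 0:
        return ChromosomePanel(chrom_id, [], chrom_length_bp)
    starts = np.asarray(
        candidates["start"] if isinstance(candidates, pd.DataFrame) else candidates,
        dtype=np.int64,
    )
    if len(starts) < n_oligo:
        raise InfeasibleDesignError(
            f"{chrom_id}: {len(starts)} candidates < {n_oligo} required per probe"
        )
    spans = _window_spans(starts, n_oligo)
    win_start = starts[: len(spans)]
    win_end = win_start + spans

    interior_lo = termini_margin_bp
    interior_hi = chrom_length_bp - termini_margin_bp
    if interior_hi - interior_lo <= 0:
        raise InfeasibleDesignError(
            f"{chrom_id}: termini margin {termini_margin_bp} leaves no interior "
            f"on a {chrom_length_bp} bp chromosome"
        )
    bin_width = (interior_hi - interior_lo) / n_probes

    probes = []
    prev_end = -np.inf
    for k in range(n_probes):
        bin_lo = interior_lo + k * bin_width
        bin_hi = interior_lo + (k + 1) * bin_width
        centre = 0.5 * (win_start + win_end)
        feasible = (
            (win_start >= interior_lo)
            & (win_end <= interior_hi)
            & (win_start >= prev_end + min_resolvable_bp)
            & (centre >= bin_lo)
            & (centre < bin_hi)
        )
        if not feasible.any():
            # relax the bin but keep hard constraints, preferring early runs
            feasible = (
                (win_start >= interior_lo)
                & (win_end <= interior_hi)
                & (win_start >= prev_end + min_resolvable_bp)
            )
        if not feasible.any():
            raise InfeasibleDesignError(
                f"{chrom_id}: no feasible window for probe {k + 1}/{n_probes} "
                f"(min gap {min_resolvable_bp}, margin {termini_margin_bp})"
            )
        idx_all = np.flatnonzero(feasible)
        best = idx_all[np.argmin(spans[idx_all])]
        rank = k + 1
        probes.append(
            Probe(
                probe_id=f"{chrom_id}_p{rank}",
                chrom_id=chrom_id,
                start_bp=int(win_start[best]),
                end_bp=int(win_end[best]),
                oligo_count=n_oligo,
                rank_on_chrom=rank,
                oligo_starts=starts[best : best + n_oligo].copy(),
            )
        )
        prev_end = win_end[best]
    return ChromosomePanel(chrom_id, probes, chrom_length_bp)


def pick_densest_1500(window) -> np.ndarray:
    """From a sorted 3000-oligo run, keep the densest of three fixed groups.

    The groups are the index ranges [0, 1500), [750, 2250), [1500, 3000)
    (start-to-middle, first-quarter-to-third-quarter, middle-to-end); the
    one with the smallest genomic span wins, earliest group on ties.
    Returns the selected oligo start positions (or row subframe).
    """
    is_frame = isinstance(window, pd.DataFrame)
    starts = np.asarray(window["start"] if is_frame else window, dtype=np.int64)
    if len(starts) != 3000:
        raise WindowSizeError(f"window has {len(starts)} oligos, expected 3000")
    groups = [(0, 1500), (750, 2250), (1500, 3000)]
    spans = [starts[hi - 1] + OLIGO_LEN - starts[lo] for lo, hi in groups]
    lo, hi = groups[int(np.argmin(spans))]
    return window.iloc[lo:hi] if is_frame else starts[lo:hi]


def assign_pair_alternation(window, colour: ColourToken) -> dict:
    """Split a window's oligos alternately between the two fluorophores.

    Oligo 1, 3, 5, ... (1-based) go to the first fluorophore in canonical
    order, oligo 2, 4, 6, ... to the second; both halves span the same
    genomic window.
    """
    if not colour.is_paired:
        raise PanelError(f"colour {colour.code} is not a two-fluorophore token")
    f1, f2 = sorted(colour.fluorophores, key=("FAM", "A550", "A647").index)
    is_frame = isinstance(window, pd.DataFrame)
    if is_frame:
        return {f1: window.iloc[0::2], f2: window.iloc[1::2]}
    arr = np.asarray(window)
    return {f1: arr[0::2], f2: arr[1::2]}


# ---------------------------------------------------------------------------
# panel summary


def panel_row(panel: ChromosomePanel) -> PanelRow:
    """Summary statistics for one chromosome panel."""
    if len(panel.probes) == 0:
        raise PanelError(f"{panel.chrom_id}: zero-probe chromosome cannot be summarised")
    dens = [p.density_oligo_per_kb for p in panel.probes]
    cov = [p.span_bp / 1000.0 for p in panel.probes]
    gaps = [
        (nxt.start_bp - prv.end_bp) / 1e6
        for prv, nxt in zip(panel.probes, panel.probes[1:])
    ]
    first, last = panel.probes[0], panel.probes[-1]
    dist_ends = 0.5 * (first.start_bp + (panel.chrom_length_bp - last.end_bp)) / 1e6
    return PanelRow(
        chrom_id=panel.chrom_id,
        n_probes=len(panel.probes),
        mean_density=float(np.mean(dens)),
        mean_coverage_kb=float(np.mean(cov)),
        mean_interprobe_mb=float(np.mean(gaps)) if gaps else float("nan"),
        mean_dist_from_ends_mb=float(dist_ends),
    )


def overall_from_rows(rows: Sequence[PanelRow]) -> tuple:
    """Overall panel statistics from per-chromosome rows.

    The total probe count is the sum over chromosomes; every other overall
    statistic is the unweighted mean of the per-chromosome means, with the
    sample standard deviation (n-1 denominator) reported alongside.
    Single-probe chromosomes contribute no interprobe value.
    """

    def _stats(values):
        v = np.asarray([x for x in values if np.isfinite(x)], dtype=float)
        sd = float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
        return float(np.mean(v)), sd

    overall = {"n_probes": int(sum(r.n_probes for r in rows))}
    sds = {}
    for key in (
        "mean_density",
        "mean_coverage_kb",
        "mean_interprobe_mb",
        "mean_dist_from_ends_mb",
    ):
        overall[key], sds[key] = _stats(getattr(r, key) for r in rows)
    return overall, sds


def summarize_panel(panels: Iterable[ChromosomePanel]) -> PanelSummary:
    """Per-chromosome rows plus the overall (unweighted mean / sample SD) row."""
    rows = [panel_row(p) for p in panels]
    overall, sds = overall_from_rows(rows)
    return PanelSummary(rows=rows, overall=overall, overall_sd=sds)


# ---------------------------------------------------------------------------
# serialisation

_RGB = {
    "FAM": (0, 200, 0),
    "A550": (255, 160, 0),
    "A647": (230, 0, 0),
    "FAM+A550": (200, 200, 0),
    "FAM+A647": (0, 170, 170),
    "A550+A647": (255, 0, 170),
}


def panels_to_frame(panels: Iterable[ChromosomePanel]) -> pd.DataFrame:
    recs = []
    for panel in panels:
        for p in panel.probes:
            recs.append(
                {
                    "probe_id": p.probe_id,
                    "chrom": p.chrom_id,
                    "start": p.start_bp,
                    "end": p.end_bp,
                    "n_oligo": p.oligo_count,
                    "colour": p.colour.code if p.colour else "",
                    "density_oligo_per_kb": round(p.density_oligo_per_kb, 4),
                    "rank": p.rank_on_chrom,
                }
            )
    return pd.DataFrame(recs)


def write_panel_bed9(panels: Iterable[ChromosomePanel], path) -> None:
    """Panel as BED9; itemRgb encodes the colour token."""
    with open(path, "w") as fh:
        for panel in panels:
            for p in panel.probes:
                rgb = _RGB.get(p.colour.code, (128, 128, 128)) if p.colour else (128, 128, 128)
                fh.write(
                    "\t".join(
                        map(
                            str,
                            [
                                p.chrom_id,
                                p.start_bp,
                                p.end_bp,
                                p.probe_id,
                                0,
                                ".",
                                p.start_bp,
                                p.end_bp,
                                ",".join(map(str, rgb)),
                            ],
                        )
                    )
                    + "\n"
                )


def panels_from_frame(df: pd.DataFrame, genome: GenomeBuild) -> dict:
    """Rebuild ChromosomePanel objects from the TSV representation."""
    panels = {}
    lengths = genome.lengths
    for chrom, sub in df.groupby("chrom", sort=False):
        chrom = str(chrom)
        if chrom not in lengths:
            raise UnknownChromosomeError(f"chromosome {chrom!r} not in genome build")
        sub = sub.sort_values("rank")
        probes = [
            Probe(
                probe_id=str(r.probe_id),
                chrom_id=chrom,
                start_bp=int(r.start),
                end_bp=int(r.end),
                oligo_count=int(r.n_oligo),
                colour=ColourToken.from_code(r.colour) if r.colour else None,
                rank_on_chrom=int(r.rank),
            )
            for r in sub.itertuples(index=False)
        ]
        panels[chrom] = ChromosomePanel(chrom, probes, lengths[chrom])
    return panels
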