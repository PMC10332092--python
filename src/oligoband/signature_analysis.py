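"""Banding-signature analysis of traced chromosomes.

Re-implements the analysis chain natively: extract per-channel intensity
along a traced path, call colour bands against a robust per-channel
threshold, build an ordered colour Signature, match it to the reference
colour scheme in both orientations by token-level Levenshtein distance, and
— when a signature deviates — search two-donor split decompositions and
single-token insertions to call rearrangements with genomic breakpoint
intervals bounded by the flanking probe coordinates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .colour_scheme import (
    FLUOROPHORES,
    ColourToken,
    Scheme,
    levenshtein,
    levenshtein_table,
)
from .errors import ProfileError, RearrangementError, SchemeError, SignatureError
from .panel_design import ChromosomePanel

DEFAULT_K_MAD = 7.0
DEFAULT_MIN_BAND_FRAC = 0.005
DEFAULT_MERGE_FRAC = 0.02
DEFAULT_MAX_ERR = 1


@dataclass
class TracedPath:
    roi_id: str
    points: np.ndarray  # (n, 2) of (x, y) pixel coordinates
    image_ref: str = ""

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
            raise ProfileError(f"trace {self.roi_id}: need >= 2 (x, y) points")
        if np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
            raise ProfileError(f"trace {self.roi_id}: consecutive points must be distinct")
        self.points = pts


@dataclass
class ChannelProfile:
    channel: str
    samples: np.ndarray
    step_px: float

    def __len__(self):
        return len(self.samples)


@dataclass
class BandCall:
    start_frac: float
    end_frac: float
    channels: frozenset
    peak_intensity: dict

    def __post_init__(self):
        if not self.start_frac < self.end_frac:
            raise SignatureError("band start must precede band end")

    @property
    def token(self) -> ColourToken:
        return ColourToken(frozenset(self.channels))

    @property
    def centre(self) -> float:
        return 0.5 * (self.start_frac + self.end_frac)


@dataclass
class Signature:
    roi_id: str
    tokens: list
    band_positions: list  # of (start_frac, end_frac)

    def __len__(self):
        return len(self.tokens)

    def codes(self) -> list:
        return [t.code for t in self.tokens]


@dataclass
class MatchResult:
    roi_id: str
    best_chrom: str
    orientation: str  # "forward" | "reverse"
    err: int
    ref_tokens: list
    low_confidence: bool = False


@dataclass
class RearrangementCall:
    type: str  # normal | translocation | reciprocal_translocation_candidate | insertion | unknown
    donors: tuple = ()
    split_index: tuple = ()  # forward-orientation gap index per donor
    orientations: tuple = ()
    signature_split: int | None = None
    cost: int = 0
    roi_id: str = ""
    inserted_token: ColourToken | None = None
    breakpoint_intervals: dict = field(default_factory=dict)
    supporting_spreads: int = 0
    notes: list = field(default_factory=list)
    #: equal-cost alternative decompositions as (donors, split_index,
    #: orientations) tuples, primary included first
    alternatives: list = field(default_factory=list)
    #: for translocation calls whose signature is also an exact single-token
    #: insertion on one chromosome; spread-level inventory may prefer it
    insertion_alternative: "RearrangementCall | None" = None


# ---------------------------------------------------------------------------
# profile extraction


def resample_path(points: np.ndarray, step_px: float = 1.0) -> np.ndarray:
    """Resample a polyline at equal arc-length steps, endpoints included."""
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    n = max(2, int(round(total / step_px)) + 1)
    s = np.linspace(0.0, total, n)
    x = np.interp(s, cum, pts[:, 0])
    y = np.interp(s, cum, pts[:, 1])
    return np.column_stack([x, y])


def extract_profile(
    image: np.ndarray,
    channels: Sequence[str],
    path: TracedPath,
    half_width_px: float = 2.0,
    step_px: float = 1.0,
) -> dict:
    """Per-channel mean intensity along the trace.

    ``image`` has shape (C, H, W); at each equal-arc-length sample the
    intensity is averaged over a segment perpendicular to the path of total
    length 2 x ``half_width_px``.  Returns {channel: ChannelProfile}, one
    entry per requested channel (DAPI included when present).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[0] != len(channels):
        raise ProfileError(
            f"image has {image.shape[0] if image.ndim == 3 else 1} channel(s), "
            f"{len(channels)} requested"
        )
    h, w = image.shape[1:]
    pts = resample_path(path.points, step_px)
    if np.any(pts[:, 0] < 0) or np.any(pts[:, 0] > w - 1) or np.any(
        pts[:, 1] < 0
    ) or np.any(pts[:, 1] > h - 1):
        raise ProfileError(f"trace {path.roi_id} exits the image bounds")

    tangent = np.gradient(pts, axis=0)
    norm = np.linalg.norm(tangent, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    tangent /= norm
    normal = np.column_stack([-tangent[:, 1], tangent[:, 0]])

    n_off = max(1, int(round(2 * half_width_px)) + 1)
    offsets = np.linspace(-half_width_px, half_width_px, n_off)
    # sample grid: (n_samples, n_offsets, 2)
    grid = pts[:, None, :] + offsets[None, :, None] * normal[:, None, :]
    xs = np.clip(grid[..., 0], 0, w - 1)
    ys = np.clip(grid[..., 1], 0, h - 1)

    profiles = {}
    for ci, ch in enumerate(channels):
        vals = ndimage.map_coordinates(
            image[ci], [ys.ravel(), xs.ravel()], order=1, mode="nearest"
        ).reshape(xs.shape)
        profiles[ch] = ChannelProfile(ch, vals.mean(axis=1), step_px)
    return profiles


# ---------------------------------------------------------------------------
# band calling


def _runs_above(mask: np.ndarray, min_len: int) -> list:
    runs = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            if i - start >= min_len:
                runs.append((start, i))
            start = None
    if start is not None and len(mask) - start >= min_len:
        runs.append((start, len(mask)))
    return runs


# standard normal quantiles for the sliding background windows
_BG_WINDOWS = (
    (2.0, 27.0, -2.0537, -0.6128),
    (10.0, 35.0, -1.2816, -0.3853),
    (20.0, 45.0, -0.8416, -0.1257),
    (30.0, 55.0, -0.5244, 0.1257),
)


def _background_from_quantiles(x: np.ndarray) -> tuple:
    """(mu, sigma) of the background lump, robust to any band fraction."""
    best = None
    for ql, qh, zl, zh in _BG_WINDOWS:
        pl, ph = np.percentile(x, [ql, qh])
        sigma = (ph - pl) / (zh - zl)
        mu = pl - zl * sigma
        if best is None or sigma < best[1]:
            best = (mu, sigma)
    return best


def _split_run_at_valleys(x: np.ndarray, s: int, e: int, baseline: float) -> list:
    """Split an above-threshold run containing several bands.

    With low-noise profiles (image extraction averages most noise away) the
    threshold sits close to background and neighbouring bands of one channel
    can share a single run; distinct peaks with prominence of at least 40%
    of the run height are separated at the deepest valley between them.
    """
    from scipy.signal import find_peaks

    seg = x[s:e]
    height = seg.max() - baseline
    if height <= 0 or e - s < 4:
        return [(s, e)]
    peaks, _ = find_peaks(seg, prominence=0.4 * height)
    if len(peaks) < 2:
        return [(s, e)]
    out = []
    start = s
    for left, right in zip(peaks, peaks[1:]):
        valley = int(np.argmin(seg[left:right])) + left
        out.append((start, s + valley))
        start = s + valley
    out.append((start, e))
    return out


def _reciprocal_overlap(a, b) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def call_bands(
    profiles: Mapping[str, ChannelProfile],
    k_mad: float = DEFAULT_K_MAD,
    min_band_frac: float = DEFAULT_MIN_BAND_FRAC,
    merge_frac: float = DEFAULT_MERGE_FRAC,
    smooth_sigma: float = 2.5,
) -> list:
    """Call colour bands from per-channel profiles.

    Each channel is Gaussian-smoothed (``smooth_sigma`` samples, 0 to
    disable) and thresholded at background + k_mad x MAD in two passes: a
    first loose pass locates candidate bands using a lower-quantile
    background estimate (robust even when bands cover a third of the
    trace), those regions are masked, and the definitive median + MAD
    threshold is computed from the signal-free remainder.  Samples above
    threshold form candidate runs (length >= min_band_frac of the profile).
    Runs in different channels with >= 50% reciprocal overlap fuse into
    paired-colour bands; finally, neighbouring calls closer than
    ``merge_frac`` of the trace length (centre to centre) fuse into one
    call when the combined fluorophore set still names a valid token.  DAPI
    is ignored here.
    """
    fluor = {ch: p for ch, p in profiles.items() if ch in FLUOROPHORES}
    if not fluor:
        raise ProfileError("no fluorophore channel among profiles")
    n = len(next(iter(fluor.values())).samples)
    if any(len(p.samples) != n for p in fluor.values()):
        raise ProfileError("profiles of one trace must share sample count")
    # a real band can never be narrower than the smoothing kernel
    min_len = max(2, int(round(min_band_frac * n)), int(np.ceil(2 * smooth_sigma)))

    raw = []  # (channel, start_idx, end_idx, peak)
    for ch, prof in fluor.items():
        x = np.asarray(prof.samples, dtype=float)
        if smooth_sigma > 0:
            x = ndimage.gaussian_filter1d(x, smooth_sigma, mode="nearest")
        # pass 1: background location/spread from the tightest of several
        # sliding quantile windows — bands only ever inflate the upper
        # windows, so the minimum spread tracks the background lump no
        # matter how much of the trace the bands cover
        mu_bg, sigma_bg = _background_from_quantiles(x)
        loose = mu_bg + k_mad * 0.6745 * sigma_bg
        mask = np.zeros(len(x), dtype=bool)
        pad = int(np.ceil(3 * max(smooth_sigma, 1.0)))
        for s, e in _runs_above(x > loose, 1):
            mask[max(0, s - pad) : min(len(x), e + pad)] = True
        # pass 2: refine with median + MAD over the band-free samples
        free = ~mask
        if free.sum() >= max(10, 0.25 * len(x)):
            bg = x[free]
            med = np.median(bg)
            mad = np.median(np.abs(bg - med))
        else:
            med, mad = mu_bg, 0.6745 * sigma_bg
        thr = med + k_mad * mad
        # floor: the quantile estimates are biased low on nearly band-free
        # profiles, but white noise cannot fall below the raw-profile MAD
        # scaled by the smoothing kernel's noise reduction
        unsmoothed = np.asarray(prof.samples, dtype=float)
        raw_med = np.median(unsmoothed)
        raw_mad = np.median(np.abs(unsmoothed - raw_med))
        reduction = 1.0 / np.sqrt(2 * np.sqrt(np.pi) * smooth_sigma) if smooth_sigma > 0 else 1.0
        thr = max(thr, raw_med + k_mad * raw_mad * reduction)
        # smoothing averages fewer samples at the profile ends, so narrow
        # boundary-touching runs are edge noise, not terminal bands
        edge_min = max(min_len, int(np.ceil(3 * smooth_sigma)))
        runs = []
        for s, e in _runs_above(x > thr, min_len):
            if (s == 0 or e == len(x)) and e - s < edge_min:
                continue
            runs.extend(_split_run_at_valleys(x, s, e, med))
        for s, e in runs:
            raw.append((ch, s, e, float(x[s:e].max())))

    if not raw:
        return []

    # fuse cross-channel co-located runs (connected components of >=50%
    # reciprocal overlap)
    parent = list(range(len(raw)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(raw)):
        for j in range(i + 1, len(raw)):
            if raw[i][0] != raw[j][0] and _reciprocal_overlap(raw[i][1:3], raw[j][1:3]) >= 0.5:
                parent[find(j)] = find(i)

    groups: dict = {}
    for i in range(len(raw)):
        groups.setdefault(find(i), []).append(raw[i])

    calls = []
    for members in groups.values():
        chans = {m[0] for m in members}
        if len(chans) > 2:
            # cannot name a 3-fluorophore token: keep the two strongest
            best2 = sorted(members, key=lambda m: -m[3])
            chans = set()
            kept = []
            for m in best2:
                if m[0] in chans or len(chans) < 2:
                    chans.add(m[0])
                    kept.append(m)
            members = kept
        s = min(m[1] for m in members)
        e = max(m[2] for m in members)
        peaks = {}
        for m in members:
            peaks[m[0]] = max(peaks.get(m[0], 0.0), m[3])
        calls.append(BandCall(s / n, e / n, frozenset(chans), peaks))

    calls.sort(key=lambda c: c.centre)

    # merge sub-resolution neighbours; resolve residual overlaps
    merged = []
    for call in calls:
        if merged:
            prev = merged[-1]
            union = prev.channels | call.channels
            overlapping = call.start_frac < prev.end_frac
            close = call.centre - prev.centre < merge_frac
            if (overlapping or close) and len(union) <= 2:
                merged[-1] = BandCall(
                    prev.start_frac,
                    max(prev.end_frac, call.end_frac),
                    union,
                    {
                        ch: max(prev.peak_intensity.get(ch, 0.0), call.peak_intensity.get(ch, 0.0))
                        for ch in union
                    },
                )
                continue
            if overlapping:
                # a three-fluorophore pile-up cannot be named: keep the
                # stronger call
                if max(call.peak_intensity.values()) > max(prev.peak_intensity.values()):
                    merged[-1] = call
                continue
        merged.append(call)
    return merged


def build_signature(bands: Sequence[BandCall], roi_id: str = "") -> Signature:
    """Order band calls along the trace into a Signature."""
    ordered = sorted(bands, key=lambda b: b.start_frac)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.start_frac < prev.end_frac - 1e-9:
            raise SignatureError(
                f"overlapping bands after merging: "
                f"[{prev.start_frac:.3f},{prev.end_frac:.3f}) and "
                f"[{nxt.start_frac:.3f},{nxt.end_frac:.3f})"
            )
    return Signature(
        roi_id=roi_id,
        tokens=[b.token for b in ordered],
        band_positions=[(b.start_frac, b.end_frac) for b in ordered],
    )


# ---------------------------------------------------------------------------
# matching


def match_signature(sig: Signature, scheme: Scheme) -> MatchResult:
    """Best reference pattern over both orientations.

    Ties resolve to the forward orientation, then to scheme chromosome
    order.  An empty signature matches the shortest reference with
    err = its length, flagged low-confidence.
    """
    if not scheme.patterns:
        raise SchemeError("empty scheme")
    best = None
    for chrom in scheme.patterns:
        ref = scheme.patterns[chrom].tokens
        for orientation, oriented in (("forward", ref), ("reverse", ref[::-1])):
            err = levenshtein(sig.tokens, oriented)
            key = (err, 0 if orientation == "forward" else 1)
            if best is None or key < best[0]:
                best = (key, chrom, orientation, err, oriented)
    _, chrom, orientation, err, oriented = best
    return MatchResult(
        roi_id=sig.roi_id,
        best_chrom=chrom,
        orientation=orientation,
        err=err,
        ref_tokens=list(oriented),
        low_confidence=len(sig.tokens) == 0,
    )


def _oriented(tokens: list, orientation: str) -> list:
    return tokens if orientation == "forward" else tokens[::-1]


def split_match(
    sig: Signature,
    scheme: Scheme,
    max_err: int = DEFAULT_MAX_ERR,
) -> RearrangementCall | None:
    """Call a rearrangement from a deviating signature.

    Searches all two-donor decompositions sig[:k] ~ prefix of donor_i,
    sig[k:] ~ suffix of donor_j (donors and both orientations enumerated,
    non-empty prefix/suffix) with total edit cost <= ``max_err``; a
    decomposition is only reported when it beats the best single-chromosome
    match (parsimony guard).  Failing that, an exact single-token insertion
    against the best single match yields an insertion call.  Any other
    deviation is returned as type "unknown".  A signature matching some
    reference exactly returns None (normal).
    """
    single = match_signature(sig, scheme)
    if single.err == 0:
        return None
    tokens = sig.tokens
    n = len(tokens)
    chroms = list(scheme.patterns)

    # DP tables per donor x orientation: prefix costs and suffix costs
    pref_tab = {}
    suf_tab = {}
    for c in chroms:
        ref = scheme.patterns[c].tokens
        for o in ("forward", "reverse"):
            oriented = _oriented(ref, o)
            pref_tab[c, o] = levenshtein_table(tokens, oriented)
            suf_tab[c, o] = levenshtein_table(tokens[::-1], oriented[::-1])

    best_cost = None
    decomps = []  # (cost, ci, cj, oi, oj, k, gap_i, gap_j) at best_cost
    for ci in chroms:
        ni = len(scheme.patterns[ci].tokens)
        for cj in chroms:
            if ci == cj:
                continue
            nj = len(scheme.patterns[cj].tokens)
            for oi in ("forward", "reverse"):
                Di = pref_tab[ci, oi]
                for oj in ("forward", "reverse"):
                    Rj = suf_tab[cj, oj]
                    for k in range(1, n):
                        p = int(np.argmin(Di[k, 1:])) + 1
                        cost_p = int(Di[k, p])
                        s = int(np.argmin(Rj[n - k, 1:])) + 1
                        cost_s = int(Rj[n - k, s])
                        total = cost_p + cost_s
                        if total > max_err:
                            continue
                        if best_cost is None or total < best_cost:
                            best_cost = total
                            decomps = []
                        if total == best_cost:
                            gap_i = p if oi == "forward" else ni - p
                            gap_j = (nj - s) if oj == "forward" else s
                            decomps.append((total, ci, cj, oi, oj, k, gap_i, gap_j))
    # exact single-token insertion against the best single match; with a
    # run of identical tokens the position is degenerate, so the smallest
    # forward-orientation gap is the canonical report
    insertion = None
    ref = single.ref_tokens
    if len(tokens) == len(ref) + 1:
        candidates = []
        for t in range(len(tokens)):
            if tokens[:t] + tokens[t + 1 :] == ref:
                gap = t if single.orientation == "forward" else len(ref) - t
                candidates.append((gap, t))
        if candidates:
            gap, t = min(candidates)
            insertion = RearrangementCall(
                type="insertion",
                donors=(single.best_chrom,),
                split_index=(gap,),
                orientations=(single.orientation,),
                signature_split=t,
                cost=1,
                roi_id=sig.roi_id,
                inserted_token=tokens[t],
            )

    if best_cost is not None and best_cost < single.err:
        seen = set()
        alternatives = []
        for total, ci, cj, oi, oj, k, gap_i, gap_j in decomps:
            key = ((ci, cj), (gap_i, gap_j))
            if key not in seen:
                seen.add(key)
                alternatives.append(((ci, cj), (gap_i, gap_j), (oi, oj)))
        total, ci, cj, oi, oj, k, gap_i, gap_j = decomps[0]
        return RearrangementCall(
            type="translocation",
            donors=(ci, cj),
            split_index=(gap_i, gap_j),
            orientations=(oi, oj),
            signature_split=k,
            cost=total,
            roi_id=sig.roi_id,
            alternatives=alternatives,
            insertion_alternative=insertion,
        )

    if insertion is not None:
        return insertion
    return RearrangementCall(
        type="unknown",
        donors=(single.best_chrom,),
        cost=single.err,
        roi_id=sig.roi_id,
    )


def map_breakpoint(call: RearrangementCall, panels: Mapping[str, ChromosomePanel]) -> RearrangementCall:
    """Attach genomic breakpoint intervals bounded by flanking probes.

    An internal gap g maps to (end of probe g, start of probe g+1) on the
    donor; terminal gaps map to the open interval up to the chromosome end
    (or start) and are flagged "reciprocity undetermined" since no probe
    lies beyond the break.
    """
    for donor, gap in zip(call.donors, call.split_index):
        panel = panels[donor]
        nb = len(panel.probes)
        if not (0 <= gap <= nb):
            raise RearrangementError(f"split index {gap} out of range 0..{nb} on {donor}")
        if gap == 0:
            interval = (0, panel.probes[0].start_bp)
            call.notes.append(f"{donor}: p-terminal break, reciprocity undetermined")
        elif gap == nb:
            interval = (panel.probes[-1].end_bp, panel.chrom_length_bp)
            call.notes.append(f"{donor}: q-terminal break, reciprocity undetermined")
        else:
            interval = (panel.probes[gap - 1].end_bp, panel.probes[gap].start_bp)
        call.breakpoint_intervals[donor] = (donor, interval[0], interval[1])
    return call


# ---------------------------------------------------------------------------
# spread-level karyotype calling


def analyze_spread(signatures: Sequence[Signature], scheme: Scheme, max_err: int = DEFAULT_MAX_ERR) -> list:
    """Match every traced signature of one spread; returns per-trace records.

    Ambiguous translocation decompositions (equal edit cost) are re-ranked
    by within-spread consistency: a short translocated fragment that alone
    cannot name its donor is resolved towards the donor/gap pair already
    implied by another trace of the same spread (the complementary
    derivative of a reciprocal exchange).  A translocation reading whose
    donors all still have their full complement of intact homologs in the
    spread is demoted to its insertion alternative when one exists — the
    inventory contradicts a derivative origin of the material.
    """
    records = []
    for sig in signatures:
        match = match_signature(sig, scheme)
        call = split_match(sig, scheme, max_err) if match.err > 0 else None
        records.append({"signature": sig, "match": match, "call": call})

    intact = Counter(
        r["match"].best_chrom for r in records if r["match"].err == 0
    )
    # expected intact copies: diploid autosomes, single sex chromosomes
    expected = {c: 1 if c.rstrip().endswith(("X", "Y")) else 2 for c in scheme.patterns}
    for r in records:
        call = r["call"]
        if call is None or call.type != "translocation" or call.insertion_alternative is None:
            continue
        # a derivative chromosome replaces one homolog of each donor, so a
        # consistent reading needs every donor short of intact copies
        donor_pairs_consistent = any(
            all(intact[d] < expected[d] for d in donors)
            for donors, _, _ in call.alternatives
        )
        ins = call.insertion_alternative
        if not donor_pairs_consistent and intact[ins.donors[0]] < expected[ins.donors[0]]:
            r["call"] = ins

    def _alt_key(alt):
        donors, gaps, _ = alt
        return tuple(sorted(zip(donors, gaps)))

    votes = Counter()
    for r in records:
        call = r["call"]
        if call is not None and call.type == "translocation":
            for alt in call.alternatives:
                votes[_alt_key(alt)] += 1
    for r in records:
        call = r["call"]
        if call is None or call.type != "translocation" or len(call.alternatives) < 2:
            continue
        ranked = sorted(
            enumerate(call.alternatives),
            key=lambda ia: (-votes[_alt_key(ia[1])], ia[0]),
        )
        _, chosen = ranked[0]
        call.donors, call.split_index, call.orientations = chosen
    return records


def _call_key(call: RearrangementCall):
    if call.type == "translocation":
        return ("translocation", tuple(sorted(zip(call.donors, call.split_index))))
    if call.type == "insertion":
        return ("insertion", tuple(zip(call.donors, call.split_index)))
    return (call.type, call.donors)


def call_karyotype(
    spreads: Sequence[Sequence[Signature]],
    scheme: Scheme,
    expected_count: int = 38,
    min_spreads: int = 5,
    majority_frac: float = 0.8,
    max_err: int = DEFAULT_MAX_ERR,
) -> dict:
    """Aggregate per-spread signature analyses into a karyotype report.

    A rearrangement is reported only when supported by at least
    ``majority_frac`` of spreads and at least ``min_spreads`` spreads were
    analysed; everything else is demoted to the artefact list.  A
    translocation whose two derivative chromosomes are both observed within
    supporting spreads is upgraded to a reciprocal-translocation candidate.
    """
    if len(spreads) == 0:
        raise SignatureError("at least one spread required")
    per_spread = []
    support: dict = {}
    calls_by_key: dict = {}
    for signatures in spreads:
        records = analyze_spread(signatures, scheme, max_err)
        inventory = Counter(r["match"].best_chrom for r in records)
        spread_keys = Counter()
        for r in records:
            if r["call"] is not None and r["call"].type != "normal":
                key = _call_key(r["call"])
                spread_keys[key] += 1
                calls_by_key.setdefault(key, r["call"])
        for key, count in spread_keys.items():
            entry = support.setdefault(key, {"spreads": 0, "both_derivatives": 0})
            entry["spreads"] += 1
            if count >= 2:
                entry["both_derivatives"] += 1
        per_spread.append(
            {
                "n_traces": len(records),
                "inventory": dict(inventory),
                "complete": len(records) == expected_count,
                "anomalies": [k for k in spread_keys],
                "records": records,
            }
        )

    n_spreads = len(spreads)
    reported = []
    artefacts = []
    for key, entry in support.items():
        frac = entry["spreads"] / n_spreads
        call = calls_by_key[key]
        summary = {
            "type": call.type,
            "donors": call.donors,
            "split_index": call.split_index,
            "supporting_spreads": entry["spreads"],
        }
        if n_spreads >= min_spreads and frac >= majority_frac:
            if call.type == "translocation" and entry["both_derivatives"] >= majority_frac * n_spreads:
                summary["type"] = "reciprocal_translocation_candidate"
            call.supporting_spreads = entry["spreads"]
            reported.append(summary)
        else:
            artefacts.append(summary)
    return {
        "status": "normal" if not reported else "rearranged",
        "n_spreads": n_spreads,
        "calls": reported,
        "artefacts": artefacts,
        "per_spread": per_spread,
    }


# ---------------------------------------------------------------------------
# G-band nomenclature


def _short(chrom: str) -> str:
    return chrom[3:] if chrom.startswith("SSC") else chrom


def to_gband_nomenclature(call: RearrangementCall, equivalence: pd.DataFrame) -> tuple:
    """Format a call in G-band nomenclature from a user equivalence table.

    The table needs columns chrom, gap, gband (band label of the inter-probe
    gap) and, for insertions, flank_pter / flank_qter (the band labels
    flanking the gap).  Uncovered intervals render as "?" and add a warning.
    Returns (iscn_string, warnings).
    """
    warnings = []

    def _lookup(chrom, gap, column="gband"):
        sub = equivalence[(equivalence["chrom"] == chrom) & (equivalence["gap"] == gap)]
        if len(sub) == 0 or column not in equivalence.columns or pd.isna(sub.iloc[0][column]):
            warnings.append(f"no G-band equivalence for {chrom} gap {gap}")
            return "?"
        return str(sub.iloc[0][column])

    if call.type in ("translocation", "reciprocal_translocation_candidate"):
        (d1, g1), (d2, g2) = zip(call.donors, call.split_index)
        bands = (_lookup(d1, g1), _lookup(d2, g2))
        prefix = "t" if any("undetermined" in n for n in call.notes) else "rcp"
        text = f"{prefix}({_short(d1)};{_short(d2)})({bands[0]};{bands[1]})"
    elif call.type == "insertion":
        donor, gap = call.donors[0], call.split_index[0]
        fp = _lookup(donor, gap, "flank_pter")
        fq = _lookup(donor, gap, "flank_qter")
        text = f"add({_short(donor)})(pter->{fp}::?::{fq}->qter)"
    else:
        text = f"?({';'.join(_short(d) for d in call.donors)})"
        warnings.append(f"no nomenclature rule for call type {call.type}")
    return text, warnings


# ---------------------------------------------------------------------------
# I/O helpers


def traces_from_tsv(path) -> list:
    """Read traces from a TSV with columns roi_id, idx, x, y."""
    df = pd.read_csv(path, sep="\t")
    traces = []
    for roi, sub in df.groupby("roi_id", sort=False):
        sub = sub.sort_values("idx")
        traces.append(TracedPath(str(roi), sub[["x", "y"]].to_numpy(dtype=float)))
    return traces


def traces_to_tsv(traces: Iterable[TracedPath], path) -> None:
    rows = []
    for tr in traces:
        for i, (x, y) in enumerate(tr.points):
            rows.append((tr.roi_id, i, x, y))
    pd.DataFrame(rows, columns=["roi_id", "idx", "x", "y"]).to_csv(path, sep="\t", index=False)


def profiles_to_tsv(profiles: Mapping[str, ChannelProfile], path) -> None:
    df = pd.DataFrame({ch: p.samples for ch, p in profiles.items()})
    df.insert(0, "sample", np.arange(len(df)))
    df.to_csv(path, sep="\t", index=False)


def profiles_from_tsv(path, step_px: float = 1.0) -> dict:
    df = pd.read_csv(path, sep="\t")
    return {
        ch: ChannelProfile(ch, df[ch].to_numpy(dtype=float), step_px)
        for ch in df.columns
        if ch != "sample"
    }
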