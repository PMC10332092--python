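"""Synthetic ground-truth data for the whole pipeline.

Generates candidate-oligo coordinate tables, multi-channel band-intensity
profiles of (possibly derivative) chromosomes, full metaphase-spread images
with their traces, and sperm-head signal multisets — each paired with the
generating truth so analysis code can be validated without microscopy.
All generators are deterministic per seed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal.windows import tukey

from .colour_scheme import FLUOROPHORES
from .errors import SimulationError
from .panel_design import OLIGO_LEN, ChromosomePanel, GenomeBuild
from .rearrangement_model import ChromosomeCopy, GameteClass
from .signature_analysis import ChannelProfile, TracedPath

CHANNELS = (*FLUOROPHORES, "DAPI")


@dataclass
class SimulationConfig:
    rng_seed: int = 0
    candidate_rate_per_bp: float = 1 / 150
    # profile rendering
    samples_per_mb: float = 4.0
    min_samples: int = 160
    band_sigma_samples: float = 2.5
    background_mean: float = 100.0
    background_sd: float = 5.0
    snr: float = 10.0
    crosstalk: float = 0.0
    random_orientation: bool = True
    # spread images
    px_per_mb: float = 1.0
    image_shape: tuple = (768, 768)
    band_sigma_px: float = 1.6
    chrom_sigma_px: float = 1.4
    bend_amplitude: float = 0.12
    overlap_probability: float = 0.0
    max_placement_retries: int = 200
    # sperm heads
    head_width_um: float = 5.0
    head_width_sd_um: float = 0.6
    decondensation: float = 1.0
    duplication_probability: float = 0.0


# ---------------------------------------------------------------------------
# candidate coordinates


def simulate_candidates(
    genome: GenomeBuild,
    rate_per_bp: float,
    rng_seed: int = 0,
    clusters: Sequence[tuple] = (),
) -> dict:
    """Homogeneous Poisson candidate 39mer starts along each chromosome.

    ``clusters`` is an optional list of (chrom_id, centre_bp, width_bp,
    extra_rate_per_bp) dense patches.  Returns chrom -> DataFrame(start,
    end, sequence), sorted and deduplicated like ``load_candidates``.
    """
    rng = np.random.default_rng(rng_seed)
    out = {}
    for chrom, length in genome.chromosomes:
        span = max(0, length - OLIGO_LEN)
        n = rng.poisson(rate_per_bp * span) if rate_per_bp > 0 else 0
        starts = rng.integers(0, span + 1, size=n) if span else np.empty(0, dtype=int)
        extra = []
        for c_chrom, centre, width, extra_rate in clusters:
            if c_chrom != chrom:
                continue
            m = rng.poisson(extra_rate * width)
            lo = max(0, int(centre - width / 2))
            hi = min(span, int(centre + width / 2))
            extra.append(rng.integers(lo, hi + 1, size=m))
        if extra:
            starts = np.concatenate([starts, *extra])
        starts = np.unique(starts.astype(np.int64))
        out[chrom] = pd.DataFrame(
            {"start": starts, "end": starts + OLIGO_LEN, "sequence": None}
        )
    return out


# ---------------------------------------------------------------------------
# band layout of (derivative) chromosome copies


def _segment_bounds(panel: ChromosomePanel, r0: int, r1: int) -> tuple:
    """Physical bp bounds of the fragment carrying donor bands r0..r1."""
    probes = panel.probes
    n = len(probes)
    if r0 == 1:
        left = 0
    else:
        left = 0.5 * (probes[r0 - 2].end_bp + probes[r0 - 1].start_bp)
    if r1 == n:
        right = panel.chrom_length_bp
    else:
        right = 0.5 * (probes[r1 - 1].end_bp + probes[r1].start_bp)
    return left, right


INSERTED_SEGMENT_BP = 8_000_000


def band_layout(copy: ChromosomeCopy, panels: Mapping[str, ChromosomePanel]) -> tuple:
    """(total_bp, [(position_bp, BandRef)]) along a chromosome copy.

    Contiguous runs of bands from the same donor are mapped through the
    donor panel's probe coordinates; fragment boundaries fall at inter-probe
    gap midpoints (or chromosome ends for terminal fragments).  Reversed
    fragments mirror their internal coordinates; inserted material of
    unknown origin gets a fixed-size nominal segment.
    """
    bands = copy.bands
    runs = []
    i = 0
    while i < len(bands):
        j = i + 1
        if bands[i].donor != "?":
            step = 0
            while (
                j < len(bands)
                and bands[j].donor == bands[i].donor
                and bands[j].donor != "?"
            ):
                d = bands[j].rank - bands[j - 1].rank
                if step == 0 and d in (1, -1):
                    step = d
                elif d != step:
                    break
                j += 1
        runs.append(bands[i:j])
        i = j

    total = 0.0
    placed = []
    for run in runs:
        if run[0].donor == "?":
            seg_len = INSERTED_SEGMENT_BP
            for idx, b in enumerate(run):
                placed.append((total + seg_len * (idx + 0.5) / len(run), b))
        else:
            panel = panels[run[0].donor]
            ranks = [b.rank for b in run]
            r_lo, r_hi = min(ranks), max(ranks)
            left, right = _segment_bounds(panel, r_lo, r_hi)
            seg_len = right - left
            reversed_run = len(run) > 1 and ranks[1] < ranks[0]
            for b in run:
                mid = panel.probes[b.rank - 1].midpoint_bp
                off = (right - mid) if reversed_run else (mid - left)
                placed.append((total + off, b))
        total += seg_len
    return total, placed


# ---------------------------------------------------------------------------
# intensity profiles


def simulate_profile(
    copy: ChromosomeCopy,
    panels: Mapping[str, ChromosomePanel],
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple:
    """Multi-channel intensity profiles of one traced chromosome copy.

    Each band adds a Gaussian bump of amplitude snr x background_sd to the
    channels of its colour token; DAPI is a smooth full-length envelope.
    Returns ({channel: ChannelProfile}, truth dict); the truth records the
    copy name, applied orientation, band fractions and token codes.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.rng_seed if rng is None else rng)
    total_bp, placed = band_layout(copy, panels)
    n = max(config.min_samples, int(round(total_bp / 1e6 * config.samples_per_mb)))
    amp = config.snr * config.background_sd

    signal = {ch: np.zeros(n) for ch in FLUOROPHORES}
    grid = np.arange(n)
    fracs = []
    for pos_bp, band in placed:
        frac = pos_bp / total_bp
        fracs.append(frac)
        centre = frac * (n - 1)
        bump = amp * np.exp(-0.5 * ((grid - centre) / config.band_sigma_samples) ** 2)
        for ch in band.token.fluorophores:
            signal[ch] += bump

    if config.crosstalk > 0:
        clean = {ch: s.copy() for ch, s in signal.items()}
        for ch in FLUOROPHORES:
            others = [clean[o] for o in FLUOROPHORES if o != ch]
            signal[ch] = clean[ch] + config.crosstalk * sum(others)

    flipped = bool(config.random_orientation and rng.random() < 0.5)
    profiles = {}
    for ch in FLUOROPHORES:
        s = signal[ch]
        if flipped:
            s = s[::-1]
        noise = rng.normal(config.background_mean, config.background_sd, size=n)
        profiles[ch] = ChannelProfile(ch, s + noise, step_px=1.0)
    dapi = config.background_mean + amp * tukey(n, alpha=0.25)
    if flipped:
        dapi = dapi[::-1]
    profiles["DAPI"] = ChannelProfile(
        "DAPI", dapi + rng.normal(0, config.background_sd, size=n), step_px=1.0
    )

    truth = {
        "name": copy.name,
        "orientation": "reverse" if flipped else "forward",
        "band_fracs": [1 - f for f in fracs][::-1] if flipped else fracs,
        "tokens": [b.token.code for _, b in placed][::-1]
        if flipped
        else [b.token.code for _, b in placed],
        "total_bp": total_bp,
    }
    return profiles, truth


# ---------------------------------------------------------------------------
# spread images


def _render_blob(img: np.ndarray, x: float, y: float, amp: float, sigma: float) -> None:
    h, w = img.shape
    r = int(3 * sigma) + 1
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1)
    ys = np.arange(y0, y1)
    gx = np.exp(-0.5 * ((xs - x) / sigma) ** 2)
    gy = np.exp(-0.5 * ((ys - y) / sigma) ** 2)
    img[y0:y1, x0:x1] += amp * gy[:, None] * gx[None, :]


def _chromosome_curve(
    rng: np.random.Generator,
    length_px: float,
    shape: tuple,
    bend_amplitude: float,
    margin: float,
    anchor: np.ndarray | None = None,
    max_retries: int = 200,
) -> np.ndarray:
    h, w = shape
    for _ in range(max_retries):
        if anchor is None:
            start = np.array(
                [rng.uniform(margin, w - margin), rng.uniform(margin, h - margin)]
            )
        else:
            start = anchor + rng.normal(0, 4, size=2)
        theta = rng.uniform(0, 2 * np.pi)
        direction = np.array([np.cos(theta), np.sin(theta)])
        normal = np.array([-direction[1], direction[0]])
        t = np.linspace(0, 1, max(8, int(length_px)))
        bend = bend_amplitude * length_px * np.sin(np.pi * t * rng.uniform(0.8, 1.6))
        pts = start[None, :] + t[:, None] * length_px * direction[None, :] + bend[:, None] * normal[None, :]
        if (
            pts[:, 0].min() >= margin
            and pts[:, 0].max() <= w - margin
            and pts[:, 1].min() >= margin
            and pts[:, 1].max() <= h - margin
        ):
            return pts
    raise SimulationError("chromosome placement failed after max retries")


def simulate_spread_image(
    copies: Sequence[ChromosomeCopy],
    panels: Mapping[str, ChromosomePanel],
    config: SimulationConfig,
    rng_seed: int | None = None,
) -> tuple:
    """Render a metaphase spread: (image (4,H,W), channels, traces, truths).

    Each chromosome copy becomes a random smooth curve; DAPI stains the
    whole curve, bands add fluorophore blobs at their layout fractions.  The
    true curve is emitted as the trace for the analyzer.  With
    ``overlap_probability`` a copy is anchored next to a previously placed
    one, and the event is recorded in its truth entry.
    """
    rng = np.random.default_rng(config.rng_seed if rng_seed is None else rng_seed)
    h, w = config.image_shape
    image = np.zeros((len(CHANNELS), h, w), dtype=float)
    chan_index = {ch: i for i, ch in enumerate(CHANNELS)}
    amp = config.snr * config.background_sd

    traces, truths, anchors = [], [], []
    for idx, copy in enumerate(copies):
        total_bp, placed = band_layout(copy, panels)
        length_px = max(10.0, total_bp / 1e6 * config.px_per_mb)
        overlapped = bool(anchors and rng.random() < config.overlap_probability)
        anchor = anchors[rng.integers(len(anchors))] if overlapped else None
        pts = _chromosome_curve(
            rng,
            length_px,
            (h, w),
            config.bend_amplitude,
            margin=4 + 3 * config.band_sigma_px,
            anchor=anchor,
            max_retries=config.max_placement_retries,
        )
        anchors.append(pts[len(pts) // 2])

        flipped = bool(config.random_orientation and rng.random() < 0.5)
        drawn = pts[::-1] if flipped else pts

        dapi = image[chan_index["DAPI"]]
        for x, y in drawn[:: max(1, len(drawn) // int(length_px))]:
            _render_blob(dapi, x, y, amp * 0.6, config.chrom_sigma_px)

        seg = np.linalg.norm(np.diff(drawn, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        for pos_bp, band in placed:
            frac = pos_bp / total_bp
            s = frac * cum[-1]
            i = np.searchsorted(cum, s, side="right") - 1
            i = min(i, len(drawn) - 2)
            t = (s - cum[i]) / max(seg[i], 1e-9)
            x, y = drawn[i] * (1 - t) + drawn[i + 1] * t
            for ch in band.token.fluorophores:
                _render_blob(image[chan_index[ch]], x, y, amp, config.band_sigma_px)

        roi = f"roi{idx:03d}"
        traces.append(TracedPath(roi, pts))
        truths.append(
            {
                "roi_id": roi,
                "name": copy.name,
                "orientation": "reverse" if flipped else "forward",
                "tokens": [b.token.code for _, b in placed],
                "overlapped": overlapped,
            }
        )

    noise = np.random.default_rng(
        (config.rng_seed if rng_seed is None else rng_seed) + 1
    ).normal(config.background_mean, config.background_sd, size=image.shape)
    image = image + noise
    return image, list(CHANNELS), traces, truths


# ---------------------------------------------------------------------------
# sperm heads


def simulate_sperm_heads(
    classes: Sequence[GameteClass],
    frequencies: Sequence[float],
    n_heads: int,
    config: SimulationConfig,
    rng_seed: int | None = None,
) -> list:
    """Draw sperm heads from a gamete-class mixture.

    Each head carries the expected signal multiset of its class; with
    probability duplication_probability x decondensation one random signal
    is duplicated (the over-decondensation artifact).  Head widths are drawn
    around the configured optimum.  Returns records with the true class
    label, the observed signal Counter, the head width and an artifact flag.
    """
    freqs = np.asarray(frequencies, dtype=float)
    if not np.isclose(freqs.sum(), 1.0):
        raise SimulationError(f"class frequencies sum to {freqs.sum()}, expected 1")
    rng = np.random.default_rng(config.rng_seed if rng_seed is None else rng_seed)
    p_dup = min(1.0, config.duplication_probability * config.decondensation)

    heads = []
    for _ in range(n_heads):
        ci = rng.choice(len(classes), p=freqs)
        gc = classes[ci]
        signals = Counter(gc.expected_signals)
        duplicated = bool(rng.random() < p_dup)
        if duplicated and signals:
            keys = sorted(signals, key=repr)
            k = keys[rng.integers(len(keys))]
            signals[k] += 1
        heads.append(
            {
                "true_class": gc.label,
                "true_balanced": gc.balanced,
                "signals": signals,
                "head_width_um": float(
                    rng.normal(config.head_width_um, config.head_width_sd_um)
                ),
                "duplication_artifact": duplicated,
            }
        )
    return heads
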