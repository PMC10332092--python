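"""Bundled pig-like reference fixture.

Ships the published per-chromosome statistics of the reference pig
oligo-banding panel (probe counts, mean density, coverage, interprobe
distance and distance from ends), approximate chromosome sizes, and
deterministic builders for a demo panel and colour scheme, so that the
documented demo recipes and the test suite run without any download.
"""

from __future__ import annotations

from functools import lru_cache

from .colour_scheme import A550, Scheme, optimize_scheme
from .panel_design import ChromosomePanel, GenomeBuild, PanelRow, Probe
from .rearrangement_model import Rearrangement

#: Approximate chromosome lengths (bp) of the pig reference assembly.
PIG_CHROM_SIZES = (
    ("SSC1", 274_330_532),
    ("SSC2", 151_935_994),
    ("SSC3", 132_848_913),
    ("SSC4", 130_910_915),
    ("SSC5", 104_526_007),
    ("SSC6", 170_843_587),
    ("SSC7", 121_844_099),
    ("SSC8", 138_966_237),
    ("SSC9", 139_512_083),
    ("SSC10", 69_359_453),
    ("SSC11", 79_169_978),
    ("SSC12", 61_602_749),
    ("SSC13", 208_334_590),
    ("SSC14", 141_755_446),
    ("SSC15", 140_412_725),
    ("SSC16", 79_944_280),
    ("SSC17", 63_494_081),
    ("SSC18", 55_982_971),
    ("SSCX", 125_939_595),
    ("SSCY", 43_547_828),
)

#: Published per-chromosome summary rows of the reference panel:
#: (chrom, n_probes, mean density oligo/kb, mean coverage kb,
#:  mean interprobe distance Mb, mean distance from ends Mb).
REFERENCE_PANEL_STATS = (
    ("SSC1", 11, 7.95, 407.14, 25.62, 6.83),
    ("SSC2", 6, 7.02, 472.20, 27.13, 6.73),
    ("SSC3", 5, 6.51, 489.77, 29.35, 6.50),
    ("SSC4", 5, 7.51, 435.29, 28.82, 6.74),
    ("SSC5", 4, 5.54, 567.71, 29.91, 6.26),
    ("SSC6", 6, 7.83, 417.29, 30.99, 6.70),
    ("SSC7", 5, 7.47, 422.50, 26.61, 6.64),
    ("SSC8", 5, 6.50, 529.61, 30.93, 6.29),
    ("SSC9", 5, 6.91, 462.63, 31.04, 6.52),
    ("SSC10", 3, 8.62, 392.15, 27.68, 6.41),
    ("SSC11", 3, 6.84, 467.41, 32.60, 6.28),
    ("SSC12", 3, 6.07, 529.09, 23.61, 6.39),
    ("SSC13", 11, 7.38, 317.05, 18.57, 9.55),
    ("SSC14", 5, 7.24, 421.43, 31.54, 6.74),
    ("SSC15", 5, 7.47, 440.67, 31.21, 6.68),
    ("SSC16", 3, 7.63, 410.37, 32.91, 6.45),
    ("SSC17", 3, 7.50, 421.36, 24.78, 6.33),
    ("SSC18", 3, 6.09, 524.97, 20.90, 6.31),
    ("SSCX", 4, 6.34, 517.71, 35.41, 8.82),
    ("SSCY", 2, 3.02, 524.80, 29.41, 6.55),
)

#: Probes per chromosome of the reference panel (design input, not derived).
PROBE_COUNTS = {chrom: n for chrom, n, *_ in REFERENCE_PANEL_STATS}


def pig_genome() -> GenomeBuild:
    return GenomeBuild("pig-like", PIG_CHROM_SIZES)


def reference_rows() -> list:
    """The bundled per-chromosome statistics as PanelRow objects."""
    return [
        PanelRow(chrom, n, dens, cov, inter, ends)
        for chrom, n, dens, cov, inter, ends in REFERENCE_PANEL_STATS
    ]


@lru_cache(maxsize=None)
def demo_panels() -> dict:
    """Deterministic demo panel: evenly spaced probes per chromosome.

    Terminal probes sit at the chromosome's published mean distance from the
    ends; probe spans equal the published mean coverage; interior probes are
    evenly spaced between the terminal ones.
    """
    genome = pig_genome()
    lengths = genome.lengths
    panels = {}
    for chrom, n, dens, cov_kb, _inter, ends_mb in REFERENCE_PANEL_STATS:
        length = lengths[chrom]
        span = int(round(cov_kb * 1000))
        margin = int(round(ends_mb * 1e6))
        first_mid = margin + span // 2
        last_mid = length - margin - span // 2
        if n == 1:
            mids = [0.5 * (first_mid + last_mid)]
        else:
            step = (last_mid - first_mid) / (n - 1)
            mids = [first_mid + k * step for k in range(n)]
        probes = []
        for k, mid in enumerate(mids, start=1):
            start = int(round(mid - span / 2))
            probes.append(
                Probe(
                    probe_id=f"{chrom}_p{k}",
                    chrom_id=chrom,
                    start_bp=start,
                    end_bp=start + span,
                    oligo_count=1500,
                    rank_on_chrom=k,
                )
            )
        panels[chrom] = ChromosomePanel(chrom, probes, length)
    return panels


@lru_cache(maxsize=None)
def demo_scheme(seed: int = 17, n_candidates: int = 300) -> Scheme:
    """Seeded colour scheme over the reference probe counts.

    Colours are copied onto the demo panel probes as a side effect, so
    ``demo_panels()`` and ``demo_scheme()`` agree.
    """
    scheme = optimize_scheme(PROBE_COUNTS, n_candidates=n_candidates, rng_seed=seed)
    panels = demo_panels()
    for chrom, pat in scheme.patterns.items():
        for probe, token in zip(panels[chrom].probes, pat.tokens):
            probe.colour = token
            probe.oligo_count = 3000 if token.is_paired else 1500
    return scheme


#: Named demo rearrangements on the pig-like fixture.  Gap index k means
#: "between band k and band k+1" on the donor (0 = before the first band,
#: n = after the last).
DEMO_REARRANGEMENTS = {
    "add10": Rearrangement(
        "add", ("SSC10",), (1,), inserted_material=(A550,)
    ),
    "rcp1-7": Rearrangement("rcp", ("SSC1", "SSC7"), (5, 1)),
    "rcp12-14": Rearrangement("rcp", ("SSC12", "SSC14"), (2, 2)),
    "rcp3-6": Rearrangement("rcp", ("SSC3", "SSC6"), (4, 2)),
    "t3-9": Rearrangement(
        "t_nonreciprocal",
        ("SSC3", "SSC9"),
        (1, PROBE_COUNTS["SSC9"]),
        donor_side="p",
    ),
}
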