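"""Six-colour token alphabet and karyotype colour-scheme optimization.

Bands are painted with one of three fluorophores used singly or in pairs,
giving a six-letter colour alphabet.  A karyotype colour scheme assigns one
token per probe per chromosome; schemes are scored by pairwise Levenshtein
distance between the chromosome banding patterns so that every chromosome
can be identified unambiguously from its colour sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ColourTokenError, SchemeError

FLUOROPHORES = ("FAM", "A550", "A647")

# dye names used on order sheets / detection oligos
FLUOROPHORE_LABELS = {"FAM": "6-FAM", "A550": "ATTO 550", "A647": "ATTO 647N"}


@dataclass(frozen=True)
class ColourToken:
    """A band colour: one or two fluorophores from the three-dye set."""

    fluorophores: frozenset

    def __post_init__(self):
        fl = frozenset(self.fluorophores)
        if not (1 <= len(fl) <= 2) or not fl <= set(FLUOROPHORES):
            raise ColourTokenError(f"invalid fluorophore set: {set(self.fluorophores)}")
        object.__setattr__(self, "fluorophores", fl)

    @property
    def code(self) -> str:
        ordered = sorted(self.fluorophores, key=FLUOROPHORES.index)
        return "+".join(ordered)

    @property
    def is_paired(self) -> bool:
        return len(self.fluorophores) == 2

    @classmethod
    def from_code(cls, code: str) -> "ColourToken":
        parts = code.split("+")
        return cls(frozenset(parts))

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"ColourToken({self.code})"

    def __lt__(self, other):
        return self.code < other.code


def _alphabet() -> tuple:
    singles = [ColourToken(frozenset({f})) for f in FLUOROPHORES]
    pairs = [
        ColourToken(frozenset({FLUOROPHORES[i], FLUOROPHORES[j]}))
        for i in range(3)
        for j in range(i + 1, 3)
    ]
    return tuple(singles + pairs)


#: The six valid colour tokens, in canonical order.
ALPHABET = _alphabet()

FAM = ALPHABET[0]
A550 = ALPHABET[1]
A647 = ALPHABET[2]


@dataclass
class BandingPattern:
    """Ordered colour tokens of one chromosome, p-terminus to q-terminus."""

    chrom_id: str
    tokens: list

    def __len__(self):
        return len(self.tokens)

    def codes(self) -> list:
        return [t.code for t in self.tokens]


@dataclass
class Scheme:
    """A full karyotype colour assignment with its score and provenance seed."""

    patterns: dict = field(default_factory=dict)  # chrom_id -> BandingPattern
    score: tuple | None = None  # (min_pairwise, sum_pairwise)
    seed: int | None = None

    def chrom_ids(self) -> list:
        return list(self.patterns)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "score": list(self.score) if self.score is not None else None,
            "patterns": {c: p.codes() for c, p in self.patterns.items()},
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Scheme":
        payload = json.loads(text)
        patterns = {
            c: BandingPattern(c, [ColourToken.from_code(code) for code in codes])
            for c, codes in payload["patterns"].items()
        }
        score = tuple(payload["score"]) if payload.get("score") else None
        return cls(patterns=patterns, score=score, seed=payload.get("seed"))


def levenshtein(a: Sequence, b: Sequence) -> int:
    """Unit-cost edit distance between two token sequences.

    Standard dynamic programming over substitution / insertion / deletion,
    each of cost 1.  Works on any sequences of hashable, comparable items.
    """
    n, m = len(a), len(b)
    if n == 0:
        return m
    if m == 0:
        return n
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        ai = a[i - 1]
        for j in range(1, m + 1):
            cost = 0 if ai == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return prev[m]


def levenshtein_table(a: Sequence, b: Sequence) -> np.ndarray:
    """Full DP table D where D[i, j] = levenshtein(a[:i], b[:j])."""
    n, m = len(a), len(b)
    D = np.zeros((n + 1, m + 1), dtype=np.int64)
    D[:, 0] = np.arange(n + 1)
    D[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            cost = 0 if ai == b[j - 1] else 1
            D[i, j] = min(D[i - 1, j] + 1, D[i, j - 1] + 1, D[i - 1, j - 1] + cost)
    return D


def random_scheme(
    probe_counts: Mapping[str, int],
    rng_seed: int | np.random.Generator,
    forbid_adjacent_repeat: bool = False,
) -> Scheme:
    """Draw one colour scheme uniformly over the six-token alphabet.

    Each band is drawn independently and uniformly.  With
    ``forbid_adjacent_repeat`` a band is redrawn until it differs from its
    predecessor on the same chromosome (off by default).
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    seed = None if isinstance(rng_seed, np.random.Generator) else int(rng_seed)
    patterns = {}
    for chrom, count in probe_counts.items():
        tokens = []
        for _ in range(int(count)):
            tok = ALPHABET[rng.integers(0, 6)]
            if forbid_adjacent_repeat:
                while tokens and tok == tokens[-1]:
                    tok = ALPHABET[rng.integers(0, 6)]
            tokens.append(tok)
        patterns[chrom] = BandingPattern(chrom, tokens)
    return Scheme(patterns=patterns, seed=seed)


def scheme_score(scheme: Scheme) -> tuple:
    """(min, sum) of Levenshtein distance over all unordered chromosome pairs."""
    chroms = scheme.chrom_ids()
    if len(chroms) < 2:
        raise SchemeError("scheme_score requires at least 2 chromosomes")
    dists = []
    for i in range(len(chroms)):
        ti = scheme.patterns[chroms[i]].tokens
        for j in range(i + 1, len(chroms)):
            dists.append(levenshtein(ti, scheme.patterns[chroms[j]].tokens))
    return (min(dists), sum(dists))


def optimize_scheme(
    probe_counts: Mapping[str, int],
    n_candidates: int = 1000,
    rng_seed: int = 0,
    forbid_adjacent_repeat: bool = False,
) -> Scheme:
    """Generate ``n_candidates`` random schemes and keep the best.

    Best = lexicographically greatest (min pairwise distance, sum of pairwise
    distances); ties resolved in favour of the earliest candidate, so the
    result is deterministic for a given seed.
    """
    if n_candidates < 1:
        raise SchemeError("n_candidates must be >= 1")
    rng = np.random.default_rng(rng_seed)
    best = None
    best_key = None
    for idx in range(n_candidates):
        cand = random_scheme(probe_counts, rng, forbid_adjacent_repeat)
        mn, sm = scheme_score(cand)
        key = (mn, sm, -idx)
        if best_key is None or key > best_key:
            cand.score = (mn, sm)
            cand.seed = int(rng_seed)
            best, best_key = cand, key
    return best


def scheme_to_tsv_rows(scheme: Scheme) -> Iterable[tuple]:
    for chrom, pat in scheme.patterns.items():
        for rank, tok in enumerate(pat.tokens, start=1):
            yield (chrom, rank, tok.code)
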