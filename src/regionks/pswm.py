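"""Position-specific weight matrices (PSWMs) and region scanning.

A PSWM assigns each scanned window the sum of per-position, per-base
log2-odds weights.  All matrices here are *consensus-normalized*: the best
base in every column scores exactly 0, so the consensus sequence scores 0
and every window score lies in (-inf, 0].  Higher scores (closer to zero)
therefore correspond to stronger predicted binders, and "the high-scoring
tail" is unambiguous throughout the package.

Besides plain matrices, a composite bacterial sigma70 promoter scorer is
provided: a -35 element, a variable-length spacer (15-19 bp by default)
with per-length weights, an optional conserved element directly upstream
of the -10 hexamer, and the -10 element itself.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PSWM",
    "PromoterModel",
    "ScoreSample",
    "build_pswm",
    "pswm_from_consensus",
    "score_window",
    "score_promoter",
    "scan_sequence",
    "scan_region",
    "reverse_complement",
    "read_pswm_tsv",
    "write_pswm_tsv",
    "read_meme_minimal",
    "write_meme_minimal",
    "load_promoter_model",
    "DEFAULT_POSITION_FLOOR",
]

ALPHABET = "ACGT"
#: Weight floor for a single matrix cell (used for zero-count cells without
#: pseudocount and for positions paired with an ambiguous base).  -20 bits
#: per position is far below any observable log-odds at realistic sample
#: sizes, while keeping empirical score distributions finite.
DEFAULT_POSITION_FLOOR = -20.0

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode A,C,G,T -> 0..3; any other symbol -> 4 (ambiguous)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


# ---------------------------------------------------------------------------
# PSWM


@dataclass
class PSWM:
    """Consensus-normalized log2-odds weight matrix.

    Parameters
    ----------
    weights
        Array of shape ``(width, 4)`` with base order A, C, G, T.  Column
        maxima must be exactly 0 (consensus normalization).
    background_freqs
        The four background base probabilities used to build the matrix;
        must sum to 1.
    name
        Free-form identifier, carried into scanner ids and file headers.
    """

    weights: np.ndarray
    background_freqs: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    name: str = "pswm"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.background_freqs = np.asarray(self.background_freqs, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[1] != 4:
            raise ValueError("weights must have shape (width, 4)")
        if self.weights.shape[0] < 1:
            raise ValueError("PSWM must have width >= 1")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("PSWM weights must be finite (floor -inf cells)")
        if abs(self.background_freqs.sum() - 1.0) > 1e-9:
            raise ValueError("background_freqs must sum to 1")
        colmax = self.weights.max(axis=1)
        if np.any(np.abs(colmax) > 1e-9):
            raise ValueError(
                "PSWM is not consensus-normalized (column maxima must be 0); "
                "build with build_pswm/pswm_from_consensus or subtract column "
                "maxima before constructing"
            )

    @property
    def width(self) -> int:
        return int(self.weights.shape[0])

    @property
    def min_footprint(self) -> int:
        return self.width

    @property
    def max_footprint(self) -> int:
        return self.width

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.weights.argmax(axis=1))

    def probabilities(self) -> np.ndarray:
        """Implied per-position base probabilities, p(b,i) ~ bg_b * 2**w(b,i)."""
        p = self.background_freqs[None, :] * np.exp2(self.weights)
        return p / p.sum(axis=1, keepdims=True)

    def scanner_id(self, strands: str = "both") -> str:
        return f"pswm:{self.name}:w{self.width}:{strands}"


def build_pswm(
    aligned_sites: Sequence[str],
    pseudocount: float = 0.0,
    background_freqs: Optional[Sequence[float]] = None,
    name: str = "pswm",
    position_floor: float = DEFAULT_POSITION_FLOOR,
) -> PSWM:
    """Build a consensus-normalized PSWM from aligned binding sites.

    Weights follow the standard information-theory construction

        w(b, i) = log2( (n(b,i) + q * f_b) / (n_i + q) / f_b )

    with ``q`` the total pseudocount, ``f_b`` the background frequency and
    ``n_i`` the number of unambiguous bases observed at position ``i``
    (``N`` counts toward no base).  Column maxima are then subtracted so the
    consensus scores 0; cells that would be -inf are floored at
    ``position_floor``.
    """
    sites = [s.upper() for s in aligned_sites]
    if len(sites) < 2:
        raise ValueError("need at least 2 aligned sites")
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise ValueError("aligned sites must all have the same length")
    if width == 0:
        raise ValueError("sites must be non-empty")
    bad = set("".join(sites)) - set("ACGTN")
    if bad:
        raise ValueError(f"unexpected symbols in sites: {sorted(bad)}")
    bg = (
        np.full(4, 0.25)
        if background_freqs is None
        else np.asarray(background_freqs, dtype=float)
    )
    if abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background_freqs must sum to 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")

    mat = np.stack([encode_sequence(s) for s in sites])  # (n_sites, width)
    counts = np.zeros((width, 4))
    for b in range(4):
        counts[:, b] = (mat == b).sum(axis=0)
    n_i = counts.sum(axis=1)
    if np.any(n_i == 0):
        cols = np.flatnonzero(n_i == 0) + 1
        raise ValueError(f"column(s) {cols.tolist()} contain only N")

    with np.errstate(divide="ignore"):
        probs = (counts + pseudocount * bg[None, :]) / (
            n_i + pseudocount
        )[:, None]
        w = np.log2(probs / bg[None, :])
    w = w - w.max(axis=1, keepdims=True)
    w = np.maximum(w, position_floor)
    return PSWM(weights=w, background_freqs=bg, name=name)


def pswm_from_consensus(
    consensus: str,
    strength: float,
    background_freqs: Optional[Sequence[float]] = None,
    name: Optional[str] = None,
) -> PSWM:
    """PSWM whose implied probabilities put ``strength`` on the consensus
    base and spread the remainder uniformly; ``N`` columns are uninformative
    (all-zero weights)."""
    if not 0.0 < strength <= 1.0:
        raise ValueError("strength must be in (0, 1]")
    consensus = consensus.upper()
    bg = (
        np.full(4, 0.25)
        if background_freqs is None
        else np.asarray(background_freqs, dtype=float)
    )
    width = len(consensus)
    probs = np.full((width, 4), 0.25)
    for i, b in enumerate(consensus):
        if b == "N":
            continue
        j = ALPHABET.index(b)
        probs[i] = (1.0 - strength) / 3.0
        probs[i, j] = strength
    with np.errstate(divide="ignore"):
        w = np.log2(probs / bg[None, :])
    w = w - w.max(axis=1, keepdims=True)
    w = np.maximum(w, DEFAULT_POSITION_FLOOR)
    return PSWM(weights=w, background_freqs=bg, name=name or f"cons_{consensus}")


# ---------------------------------------------------------------------------
# Composite promoter model


@dataclass
class PromoterModel:
    """Composite sigma70-style scorer.

    Elements are laid out left to right as -35, spacer, optional extension
    (the conserved bases directly upstream of -10), -10.  A placement's
    score is the best over allowed spacer lengths of the summed element
    scores plus the spacer weight.  Spacer weights are normalized so the
    best spacer length scores 0.
    """

    pswm_minus10: PSWM
    pswm_minus35: Optional[PSWM] = None
    extension: Optional[PSWM] = None
    spacer_weights: dict[int, float] = field(default_factory=lambda: {0: 0.0})
    name: str = "promoter"

    def __post_init__(self) -> None:
        lens = sorted(self.spacer_weights)
        if not lens:
            raise ValueError("spacer_weights must be non-empty")
        if lens != list(range(lens[0], lens[-1] + 1)):
            raise ValueError("spacer lengths must form a contiguous range")
        if min(lens) < 0:
            raise ValueError("spacer lengths must be >= 0")
        top = max(self.spacer_weights.values())
        # normalize: best spacer length contributes 0
        self.spacer_weights = {
            s: float(w - top) for s, w in sorted(self.spacer_weights.items())
        }

    @property
    def spacer_range(self) -> tuple[int, int]:
        lens = sorted(self.spacer_weights)
        return lens[0], lens[-1]

    @property
    def _w35(self) -> int:
        return self.pswm_minus35.width if self.pswm_minus35 is not None else 0

    @property
    def _wext(self) -> int:
        return self.extension.width if self.extension is not None else 0

    def footprint(self, spacer: int) -> int:
        return self._w35 + spacer + self._wext + self.pswm_minus10.width

    @property
    def min_footprint(self) -> int:
        return self.footprint(self.spacer_range[0])

    @property
    def max_footprint(self) -> int:
        return self.footprint(self.spacer_range[1])

    def scanner_id(self, strands: str = "both") -> str:
        return f"promoter:{self.name}:f{self.max_footprint}:{strands}"


Scorer = Union[PSWM, PromoterModel]


# ---------------------------------------------------------------------------
# Scoring


def _extended_weights(pswm: PSWM, floor: float) -> np.ndarray:
    """(width, 5) weights with column 4 = per-position floor for ambiguous bases."""
    return np.hstack([pswm.weights, np.full((pswm.width, 1), floor)])


def score_window(
    model: PSWM, window: str, position_floor: float = DEFAULT_POSITION_FLOOR
) -> float:
    """Score one window of exactly the matrix width (forward strand)."""
    if len(window) != model.width:
        raise ValueError(
            f"window length {len(window)} != matrix width {model.width}"
        )
    enc = encode_sequence(window)
    w = _extended_weights(model, position_floor)
    return float(w[np.arange(model.width), enc].sum())


def _pswm_position_scores(
    pswm: Optional[PSWM], enc: np.ndarray, floor: float
) -> np.ndarray:
    """Scores of the matrix at every start position (len L - w + 1); a
    ``None`` matrix behaves as width 0 (all-zero scores at every position)."""
    L = enc.size
    if pswm is None:
        return np.zeros(L + 1)
    w = pswm.width
    n = L - w + 1
    if n <= 0:
        return np.zeros(0)
    ext = _extended_weights(pswm, floor)
    out = np.zeros(n)
    for j in range(w):
        out += ext[j, enc[j : j + n]]
    return out


def _scan_forward(
    scorer: Scorer, enc: np.ndarray, floor: float
) -> np.ndarray:
    """Forward-strand placement scores for an encoded sequence."""
    if isinstance(scorer, PSWM):
        return _pswm_position_scores(scorer, enc, floor)
    L = enc.size
    F = scorer.max_footprint
    n = L - F + 1
    if n <= 0:
        return np.zeros(0)
    s35 = _pswm_position_scores(scorer.pswm_minus35, enc, floor)
    sext = _pswm_position_scores(scorer.extension, enc, floor)
    s10 = _pswm_position_scores(scorer.pswm_minus10, enc, floor)
    w35, wext = scorer._w35, scorer._wext
    best = np.full(n, -np.inf)
    for s, sw in scorer.spacer_weights.items():
        a = s35[:n] if w35 else 0.0
        b = sext[w35 + s : w35 + s + n] if wext else 0.0
        c = s10[w35 + s + wext : w35 + s + wext + n]
        np.maximum(best, a + sw + b + c, out=best)
    return best


def score_promoter(
    model: PromoterModel,
    seq: str,
    offset: int = 0,
    position_floor: float = DEFAULT_POSITION_FLOOR,
) -> float:
    """Best composite score for a placement starting at ``offset``.

    The sequence must be long enough to hold the maximal footprint at that
    offset, so every allowed spacer length can be evaluated.
    """
    if offset < 0 or offset + model.max_footprint > len(seq):
        raise ValueError(
            f"sequence too short to hold maximal footprint "
            f"{model.max_footprint} at offset {offset}"
        )
    enc = encode_sequence(seq[offset : offset + model.max_footprint])
    return float(_scan_forward(model, enc, position_floor)[0])


def required_length(scorer: Scorer) -> int:
    """Minimum region length needed for one placement of the scanner."""
    return scorer.max_footprint


def scan_sequence(
    scorer: Scorer,
    seq: str,
    strands: str = "both",
    position_floor: float = DEFAULT_POSITION_FLOOR,
) -> np.ndarray:
    """All placement scores on a raw sequence (forward, or both strands
    pooled).  Both-strand mode scans the reverse complement identically and
    pools the scores."""
    if strands not in ("both", "forward"):
        raise ValueError("strands must be 'both' or 'forward'")
    enc = encode_sequence(seq)
    fwd = _scan_forward(scorer, enc, position_floor)
    if strands == "forward":
        return fwd
    rev = _scan_forward(
        scorer, encode_sequence(reverse_complement(seq)), position_floor
    )
    return np.concatenate([fwd, rev])


@dataclass
class ScoreSample:
    """The multiset of window scores obtained by scanning one region."""

    region_id: str
    scores: np.ndarray
    scanner_id: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)

    @property
    def n(self) -> int:
        return int(self.scores.size)


def scan_region(
    scorer: Scorer,
    region,
    strands: str = "both",
    position_floor: float = DEFAULT_POSITION_FLOOR,
) -> ScoreSample:
    """Scan a :class:`~regionks.regions.GenomicRegion` into a ScoreSample.

    For a width-``w`` PSWM on a length-``L`` region in both-strand mode the
    sample holds ``2 * (L - w + 1)`` scores.
    """
    seq = region.seq
    F = required_length(scorer)
    if len(seq) < F:
        raise ValueError(
            f"region {region.region_id!r} (length {len(seq)}) is shorter "
            f"than the scanner footprint {F}"
        )
    n_frac = seq.upper().count("N") / len(seq)
    if n_frac > 0.5:
        warnings.warn(
            f"region {region.region_id!r} is {n_frac:.0%} N; scores use the "
            "ambiguity floor",
            stacklevel=2,
        )
    scores = scan_sequence(scorer, seq, strands=strands, position_floor=position_floor)
    return ScoreSample(
        region_id=region.region_id,
        scores=scores,
        scanner_id=scorer.scanner_id(strands),
    )


# ---------------------------------------------------------------------------
# File formats


def write_pswm_tsv(pswm: PSWM, path) -> None:
    """Plain TSV: rows = positions, columns = A, C, G, T."""
    df = pd.DataFrame(pswm.weights, columns=list(ALPHABET))
    df.index.name = "pos"
    df.index = df.index + 1
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_pswm_tsv(
    path,
    background_freqs: Optional[Sequence[float]] = None,
    name: Optional[str] = None,
) -> PSWM:
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [b for b in ALPHABET if b not in df.columns]
    if missing:
        raise ValueError(f"TSV matrix is missing base column(s) {missing}")
    w = df[list(ALPHABET)].to_numpy(dtype=float)
    w = w - w.max(axis=1, keepdims=True)  # tolerate un-normalized input
    bg = (
        np.full(4, 0.25)
        if background_freqs is None
        else np.asarray(background_freqs, dtype=float)
    )
    return PSWM(weights=w, background_freqs=bg, name=name or Path(path).stem)


def read_meme_minimal(path) -> list[PSWM]:
    """Parse MEME minimal motif format; probability matrices are converted
    to consensus-normalized log2-odds with the file's background letter
    frequencies (uniform if absent)."""
    text = Path(path).read_text()
    bg = np.full(4, 0.25)
    m_bg = re.search(
        r"Background letter frequencies.*?\n([ACGT0-9.eE+\-\s]+)", text
    )
    if m_bg:
        toks = m_bg.group(1).split()
        freqs = {toks[i]: float(toks[i + 1]) for i in range(0, len(toks) - 1, 2)}
        if set("ACGT") <= set(freqs):
            bg = np.array([freqs[b] for b in ALPHABET])
            bg = bg / bg.sum()
    motifs = []
    for m in re.finditer(
        r"MOTIF\s+(\S+).*?letter-probability matrix:[^\n]*\n((?:\s*[\d.eE+\-]+[ \t]+[\d.eE+\-]+[ \t]+[\d.eE+\-]+[ \t]+[\d.eE+\-]+\s*\n?)+)",
        text,
        re.DOTALL,
    ):
        name = m.group(1)
        rows = [
            [float(x) for x in line.split()]
            for line in m.group(2).strip().splitlines()
        ]
        probs = np.asarray(rows, dtype=float)
        probs = np.clip(probs, 1e-12, None)
        probs = probs / probs.sum(axis=1, keepdims=True)
        w = np.log2(probs / bg[None, :])
        w = w - w.max(axis=1, keepdims=True)
        w = np.maximum(w, DEFAULT_POSITION_FLOOR)
        motifs.append(PSWM(weights=w, background_freqs=bg, name=name))
    if not motifs:
        raise ValueError(f"no MEME motifs found in {path}")
    return motifs


def write_meme_minimal(pswms: Iterable[PSWM], path) -> None:
    pswms = list(pswms)
    bg = pswms[0].background_freqs
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "Background letter frequencies",
        " ".join(f"{b} {f:.6f}" for b, f in zip(ALPHABET, bg)),
        "",
    ]
    for p in pswms:
        probs = p.probabilities()
        lines.append(f"MOTIF {p.name}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {p.width} "
            f"nsites= 20 E= 0"
        )
        for row in probs:
            lines.append(" ".join(f"{x:.6f}" for x in row))
        lines.append("")
    Path(path).write_text("\n".join(lines))


def load_promoter_model(path) -> PromoterModel:
    """Load a composite promoter scorer from a small YAML config.

    Keys: ``minus10`` (required), ``minus35``, ``extension`` — each a PSWM
    TSV path relative to the config file — and ``spacer_weights``, a mapping
    from spacer length to weight.
    """
    path = Path(path)
    cfg = yaml.safe_load(path.read_text())
    base = path.parent

    def _load(key):
        if cfg.get(key) is None:
            return None
        return read_pswm_tsv(base / cfg[key], name=key)

    m10 = _load("minus10")
    if m10 is None:
        raise ValueError("promoter config must reference a minus10 matrix")
    spw = {int(k): float(v) for k, v in cfg.get("spacer_weights", {0: 0}).items()}
    return PromoterModel(
        pswm_minus10=m10,
        pswm_minus35=_load("minus35"),
        extension=_load("extension"),
        spacer_weights=spw,
        name=cfg.get("name", path.stem),
    )
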