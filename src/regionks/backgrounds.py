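"""Empirical background (null) score distributions.

Two backgrounds are supported, mirroring the two natural null choices for
region-level enrichment testing:

* **randomized** — scores of sequences randomized so as to preserve
  trinucleotide statistics of the intergenic regions (an order-2 Markov
  chain fit to those regions; an exact trinucleotide-preserving shuffle is
  available as an alternative mode);
* **convergent** — pooled scores of the convergent intergenic regions,
  where functional regulator binding is not expected.  Unlike randomized
  sequence, this background carries whatever negative selection has acted
  on high-scoring non-sites, which is why it is the default choice.

Backgrounds must be scanned with exactly the same scorer configuration as
the foreground; a ``scanner_id`` string is threaded through to enforce it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .pswm import (
    Scorer,
    encode_sequence,
    required_length,
    scan_sequence,
)
from .regions import GenomicRegion

__all__ = [
    "MarkovModel",
    "BackgroundDistribution",
    "fit_markov",
    "sample_randomized",
    "shuffle_preserving_kmers",
    "build_background",
    "iid_markov",
]

ALPHABET = "ACGT"


@dataclass
class MarkovModel:
    """Fixed-order Markov chain over {A,C,G,T}.

    ``joint_probs[c, b]`` is the probability of observing context k-mer
    ``c`` followed by base ``b`` among all (order+1)-mer windows, so for
    order 2 it holds exactly the trinucleotide probabilities.  Contexts
    never observed get uniform transitions.
    """

    order: int
    joint_probs: np.ndarray  # (4**order, 4), sums to 1

    initial_probs: np.ndarray = field(init=False)
    transition_probs: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.joint_probs = np.asarray(self.joint_probs, dtype=float)
        k = 4**self.order
        if self.joint_probs.shape != (k, 4):
            raise ValueError(f"joint_probs must have shape ({k}, 4)")
        total = self.joint_probs.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError("joint_probs must sum to 1")
        self.initial_probs = self.joint_probs.sum(axis=1)
        trans = np.empty_like(self.joint_probs)
        for c in range(k):
            row_total = self.joint_probs[c].sum()
            trans[c] = (
                self.joint_probs[c] / row_total if row_total > 0 else 0.25
            )
        self.transition_probs = trans

    def kmer_probs(self) -> np.ndarray:
        """(order+1)-mer probabilities, flattened in base-4 lexicographic
        order (A=0..T=3); for order 2 these are the trinucleotide
        probabilities."""
        return self.joint_probs.reshape(-1)


def _context_indices(enc: np.ndarray, order: int) -> np.ndarray:
    """Base-4 index of each length-``order`` window of an encoded sequence
    (windows containing ambiguous bases get index -1)."""
    n = enc.size - order + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    idx = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for j in range(order):
        chunk = enc[j : j + n].astype(np.int64)
        ok &= chunk < 4
        idx = idx * 4 + np.where(chunk < 4, chunk, 0)
    idx[~ok] = -1
    return idx


def fit_markov(seqs: Sequence[str], order: int = 2) -> MarkovModel:
    """Fit a Markov chain by pooling (order+1)-mer counts across sequences
    (no counting across sequence boundaries; windows with N are skipped)."""
    if order < 1:
        raise ValueError("order must be >= 1")
    seqs = [s for s in seqs if len(s) > order]
    if not seqs:
        raise ValueError("no sequence long enough to fit the model")
    total_len = sum(len(s) for s in seqs)
    if total_len <= 4 ** (order + 1):
        warnings.warn(
            f"only {total_len} bp of training sequence for an order-{order} "
            "model; transition estimates will be noisy",
            stacklevel=2,
        )
    counts = np.zeros((4**order, 4))
    for s in seqs:
        enc = encode_sequence(s)
        ctx = _context_indices(enc, order)[:-1]
        nxt = enc[order:].astype(np.int64)
        keep = (ctx >= 0) & (nxt < 4)
        np.add.at(counts, (ctx[keep], nxt[keep]), 1.0)
    total = counts.sum()
    if total == 0:
        raise ValueError("no unambiguous (order+1)-mers in the input")
    return MarkovModel(order=order, joint_probs=counts / total)


def iid_markov(base_probs: Sequence[float], order: int = 2) -> MarkovModel:
    """A Markov model with independent bases of the given composition
    (useful as a simple generative source)."""
    p = np.asarray(base_probs, dtype=float)
    p = p / p.sum()
    k = 4**order
    ctx_p = np.ones(k)
    for j in range(order):
        digits = (np.arange(k) // 4 ** (order - 1 - j)) % 4
        ctx_p *= p[digits]
    joint = ctx_p[:, None] * p[None, :]
    return MarkovModel(order=order, joint_probs=joint)


def sample_sequence(
    model: MarkovModel, length: int, rng: np.random.Generator
) -> str:
    """Draw one sequence: initial k-mer from the context marginal, then
    chained transitions."""
    k = model.order
    if length < k:
        raise ValueError(f"length {length} < model order {k}")
    cum_init = np.cumsum(model.initial_probs)
    cum_trans = np.cumsum(model.transition_probs, axis=1)
    ctx = int(np.searchsorted(cum_init, rng.random() * cum_init[-1], side="right"))
    ctx = min(ctx, 4**k - 1)
    digits = [(ctx // 4 ** (k - 1 - j)) % 4 for j in range(k)]
    out = list(digits)
    mod = 4 ** (k - 1)
    u = rng.random(length - k)
    for t in range(length - k):
        b = int(np.searchsorted(cum_trans[ctx], u[t], side="right"))
        b = min(b, 3)
        out.append(b)
        ctx = (ctx % mod) * 4 + b
    return "".join(ALPHABET[b] for b in out)


def sample_randomized(
    model: MarkovModel,
    lengths: Sequence[int],
    rng_seed: Union[int, np.random.Generator, None] = 0,
) -> list[str]:
    """Randomized sequences of the requested lengths; deterministic under a
    fixed seed."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    return [sample_sequence(model, L, rng) for L in lengths]


def shuffle_preserving_kmers(
    seq: str, k: int = 3, rng: Union[int, np.random.Generator, None] = 0
) -> str:
    """Exact k-mer-preserving shuffle (Altschul–Erickson style Euler-path
    randomization on the (k-1)-mer transition multigraph).  The returned
    sequence has exactly the same k-mer multiset as the input."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if len(seq) <= k:
        return seq
    seq = seq.upper()
    verts = [seq[i : i + k - 1] for i in range(len(seq) - k + 2)]
    edges: dict[str, list[str]] = {}
    for a, b in zip(verts, verts[1:]):
        edges.setdefault(a, []).append(b)
    start, final = verts[0], verts[-1]
    vlist = [v for v in edges if v != final]
    for _ in range(10000):
        last = {v: edges[v][int(rng.integers(len(edges[v])))] for v in vlist}
        # accept iff following chosen last-edges from every vertex reaches `final`
        ok = True
        for v in vlist:
            seen = set()
            cur = v
            while cur != final:
                if cur in seen or cur not in last:
                    ok = False
                    break
                seen.add(cur)
                cur = last[cur]
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - practically unreachable
        raise RuntimeError("could not sample an Eulerian arborescence")
    pools = {}
    for v, outs in edges.items():
        rest = list(outs)
        if v in last:
            rest.remove(last[v])
        rng.shuffle(rest)
        if v in last:
            rest.append(last[v])
        pools[v] = rest
    walk = [start]
    cur = start
    used = {v: 0 for v in edges}
    while used.get(cur, 0) < len(edges.get(cur, [])):
        nxt = pools[cur][used[cur]]
        used[cur] += 1
        walk.append(nxt)
        cur = nxt
    return walk[0] + "".join(v[-1] for v in walk[1:])


# ---------------------------------------------------------------------------
# Background distributions


@dataclass
class BackgroundDistribution:
    """A pooled empirical score distribution with survival-function access."""

    scores: np.ndarray  # stored sorted ascending
    source: str = "custom"  # randomized | convergent | custom
    scanner_id: str = ""

    def __post_init__(self) -> None:
        self.scores = np.sort(np.asarray(self.scores, dtype=float))
        if self.scores.size == 0:
            raise ValueError("background must contain at least one score")

    @property
    def m(self) -> int:
        return int(self.scores.size)

    def survival(self, x) -> np.ndarray:
        """S(x) = fraction of pooled scores >= x."""
        x = np.asarray(x, dtype=float)
        return (self.m - np.searchsorted(self.scores, x, side="left")) / self.m

    def cdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.searchsorted(self.scores, x, side="right") / self.m

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#source={self.source}\n")
            fh.write(f"#scanner_id={self.scanner_id}\n")
            fh.write(f"#m={self.m}\n")
            for s in self.scores:
                fh.write(f"{float(s)!r}\n")

    @classmethod
    def load(cls, path) -> "BackgroundDistribution":
        meta = {}
        scores = []
        for line in Path(path).read_text().splitlines():
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key] = val
            elif line.strip():
                scores.append(float(line))
        return cls(
            scores=np.array(scores),
            source=meta.get("source", "custom"),
            scanner_id=meta.get("scanner_id", ""),
        )


def build_background(
    inputs: Sequence[Union[GenomicRegion, str]],
    scorer: Scorer,
    strands: str = "both",
    source: str = "custom",
    min_windows: int = 1000,
) -> BackgroundDistribution:
    """Scan regions (or raw sequences) and pool all window scores into one
    empirical background.  Regions shorter than the scanner footprint are
    skipped; at least one region must be scannable."""
    F = required_length(scorer)
    pooled = []
    for item in inputs:
        seq = item.seq if isinstance(item, GenomicRegion) else item
        if len(seq) < F:
            continue
        pooled.append(scan_sequence(scorer, seq, strands=strands))
    if not pooled:
        raise ValueError(
            f"no input region is long enough for the scanner footprint {F}"
        )
    scores = np.concatenate(pooled)
    if scores.size < min_windows:
        warnings.warn(
            f"background holds only {scores.size} windows (< {min_windows}); "
            "tail estimates will be unstable",
            stacklevel=2,
        )
    return BackgroundDistribution(
        scores=scores, source=source, scanner_id=scorer.scanner_id(strands)
    )
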