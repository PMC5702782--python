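"""Synthetic annotated genomes with planted regulator targets.

The generator lays out an alternating gene/gap chromosome whose gap
classes (convergent vs. other intergenic) follow from the sampled gene
strands, plants motif instances into a labeled subset of the other
intergenic gaps, and optionally applies *negative selection*: chance
high-scoring non-sites are rejection-resampled out of the regions where
functional binding does not occur, which is the mechanism that makes real
unbound sequence differ from randomized sequence in the high-score tail.

Three presets mirror the canonical regimes of pleiotropic bacterial
regulators:

* ``crp_like`` — strong, information-rich sites, no negative selection;
  the pooled score distribution of the other intergenic regions shows a
  visible high-score excess.
* ``fnr_like`` — intermediate-strength palindromic sites with an
  uninformative core, no negative selection.
* ``sigma70_like`` — a weak composite promoter model (-35 / spacer /
  extended -10 / -10) with several sites per target and negative selection
  on non-sites, the hard regime where single-best-hit classification
  breaks down.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .backgrounds import (
    BackgroundDistribution,
    MarkovModel,
    build_background,
    fit_markov,
    iid_markov,
    sample_randomized,
    sample_sequence,
)
from .pswm import (
    ALPHABET,
    PSWM,
    PromoterModel,
    Scorer,
    pswm_from_consensus,
    required_length,
    reverse_complement,
    scan_sequence,
    score_window,
    score_promoter,
)
from .regions import (
    CONVERGENT,
    ORF_INTERIOR,
    OTHER,
    Gene,
    GenomicRegion,
    classify_intergenic,
    sample_orf_interior,
)

__all__ = [
    "NegativeSelection",
    "SyntheticConfig",
    "PlantedSite",
    "SyntheticTruth",
    "Bundle",
    "generate_genome",
    "benchmark_suite",
    "preset_config",
    "PRESETS",
]


@dataclass(frozen=True)
class NegativeSelection:
    """Rejection-resampling of chance high-scoring non-sites.

    Every window scoring above ``threshold`` in a region where functional
    binding does not occur is resampled from the base-composition source,
    for up to ``max_passes`` full rescans.  With ``deplete_targets`` the
    same pressure also acts on the *non-site* windows of target regions
    (planted sites are never touched), reflecting that selection removes
    non-sites wherever they arise, while functional sites sit on top of
    that depleted landscape.
    """

    on: bool = False
    threshold: float = -10.0
    max_passes: int = 30
    deplete_targets: bool = False


@dataclass
class SyntheticConfig:
    """Generator settings; defaults are overridden by the presets."""

    n_genes: int = 100
    gene_length_range: tuple[int, int] = (300, 900)
    intergenic_length_range: tuple[int, int] = (100, 300)
    #: probability of '+' strand, or an explicit pattern string like "++-+-"
    strand_assignment: Union[float, str] = 0.5
    motif: Scorer = field(
        default_factory=lambda: pswm_from_consensus("TTGACATATAAT", 0.9)
    )
    n_target_regions: int = 20
    sites_per_target: tuple[int, int] = (1, 2)
    site_strength: float = 0.9
    negative_selection: NegativeSelection = field(
        default_factory=NegativeSelection
    )
    base_composition: Optional[MarkovModel] = None
    orf_source: Optional[MarkovModel] = None
    chrom_name: str = "chr"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.site_strength <= 1.0:
            raise ValueError("site_strength must be in (0, 1]")
        if self.n_target_regions < 0:
            raise ValueError("n_target_regions must be >= 0")


@dataclass(frozen=True)
class PlantedSite:
    region_id: str
    chrom: str
    start: int  # absolute, 0-based half-open
    end: int
    strand: str
    seq: str  # site sequence on its own strand


@dataclass
class SyntheticTruth:
    """Ground-truth labels for one generated genome."""

    region_classes: dict[str, str]  # region_id -> other/convergent
    target_region_ids: list[str]
    sites: list[PlantedSite]

    def label(self, region_id: str) -> str:
        return "target" if region_id in set(self.target_region_ids) else "nontarget"


# ---------------------------------------------------------------------------
# Site emission


def _emit_from_pswm(pswm: PSWM, strength: float, rng: np.random.Generator) -> str:
    """Emit one site: at informative positions the consensus base appears
    with probability ``strength`` and otherwise a base drawn from the
    matrix's implied probabilities with the consensus removed and
    renormalized; positions with tied (uninformative) columns are drawn
    from the implied probabilities directly."""
    probs = pswm.probabilities()
    out = []
    for i in range(pswm.width):
        col = probs[i]
        w = pswm.weights[i]
        informative = (w.max() - w.min()) > 1e-9
        if not informative:
            out.append(ALPHABET[int(rng.choice(4, p=col / col.sum()))])
            continue
        ci = int(w.argmax())
        if rng.random() < strength:
            out.append(ALPHABET[ci])
        else:
            rest = col.copy()
            rest[ci] = 0.0
            rest = rest / rest.sum()
            out.append(ALPHABET[int(rng.choice(4, p=rest))])
    return "".join(out)


def _emit_site(
    motif: Scorer,
    strength: float,
    base_src: MarkovModel,
    rng: np.random.Generator,
) -> str:
    if isinstance(motif, PSWM):
        return _emit_from_pswm(motif, strength, rng)
    # composite promoter: -35, spacer (length drawn with probability
    # proportional to 2**spacer_weight), optional extension, -10
    lens = np.array(sorted(motif.spacer_weights))
    w = np.exp2([motif.spacer_weights[s] for s in lens])
    spacer_len = int(rng.choice(lens, p=w / w.sum()))
    parts = []
    if motif.pswm_minus35 is not None:
        parts.append(_emit_from_pswm(motif.pswm_minus35, strength, rng))
    if spacer_len:
        parts.append(sample_sequence(base_src, spacer_len, rng))
    if motif.extension is not None:
        parts.append(_emit_from_pswm(motif.extension, strength, rng))
    parts.append(_emit_from_pswm(motif.pswm_minus10, strength, rng))
    return "".join(parts)


def _place_sites(
    gap_seq: list[str],
    site_seqs: Sequence[str],
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Write site sequences into the gap at non-overlapping offsets drawn
    uniformly over all feasible arrangements (free space is split among the
    k+1 inter-site gaps by sampling a random composition); returns the
    occupied (start, end) intervals in the order of ``site_seqs``."""
    L = len(gap_seq)
    k = len(site_seqs)
    if k == 0:
        return []
    lens = [len(s) for s in site_seqs]
    free = L - sum(lens)
    if free < 0:
        raise ValueError(
            f"region of length {L} cannot hold {k} sites totalling {sum(lens)} bp"
        )
    order = rng.permutation(k)
    # random weak composition of `free` into k+1 parts
    cuts = np.sort(rng.choice(free + k, size=k, replace=False)) if k else []
    placed_in_order: list[tuple[int, int]] = []
    pos = 0
    prev = -1
    for rank, ci in enumerate(cuts):
        pos += int(ci) - prev - 1  # gap before this site
        prev = int(ci)
        i = order[rank]
        placed_in_order.append((i, pos))
        gap_seq[pos : pos + lens[i]] = list(site_seqs[i])
        pos += lens[i]
    placed = [None] * k
    for i, off in placed_in_order:
        placed[i] = (off, off + lens[i])
    return placed


# ---------------------------------------------------------------------------
# Negative selection


def _offending_intervals(
    seq: str,
    scorer: Scorer,
    threshold: float,
    protected: Sequence[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Forward-coordinate intervals of windows (either strand) scoring above
    the threshold and disjoint from every protected interval."""
    F = required_length(scorer)
    L = len(seq)
    if L < F:
        return []
    fwd = scan_sequence(scorer, seq, strands="forward")
    rev = scan_sequence(scorer, reverse_complement(seq), strands="forward")
    ivals = []
    for j in np.flatnonzero(fwd > threshold):
        ivals.append((int(j), int(j) + F))
    for j in np.flatnonzero(rev > threshold):
        ivals.append((L - F - int(j), L - int(j)))
    return [
        (b, e)
        for b, e in ivals
        if all(b >= pe or e <= pb for pb, pe in protected)
    ]


def _deplete(
    gap_seq: list[str],
    scorer: Scorer,
    sel: NegativeSelection,
    base_src: MarkovModel,
    protected: Sequence[tuple[int, int]],
    rng: np.random.Generator,
    local_tries: int = 80,
) -> None:
    """Rejection-resample until no unprotected window scores above the
    threshold.  Each offending stretch is resampled and immediately
    re-checked locally (so a cleaned stretch cannot silently re-offend),
    with full-region passes around that to catch windows straddling
    stretch boundaries."""
    F = required_length(scorer)
    L = len(gap_seq)
    for _ in range(sel.max_passes):
        bad = _offending_intervals("".join(gap_seq), scorer, sel.threshold, protected)
        if not bad:
            return
        bad.sort()
        merged = [list(bad[0])]
        for b, e in bad[1:]:
            if b <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([b, e])
        for b, e in merged:
            b, e = max(b, 0), min(e, L)
            lo, hi = max(0, b - F + 1), min(L, e + F - 1)
            shift = [(pb - lo, pe - lo) for pb, pe in protected]
            for _ in range(local_tries):
                gap_seq[b:e] = list(sample_sequence(base_src, e - b, rng))
                local = _offending_intervals(
                    "".join(gap_seq[lo:hi]), scorer, sel.threshold, shift
                )
                # only offenders touching the resampled span are this
                # stretch's responsibility; the rest predate it
                if not any(
                    lo + ib < e and lo + ie > b for ib, ie in local
                ):
                    break
    bad = _offending_intervals("".join(gap_seq), scorer, sel.threshold, protected)
    if bad:
        raise RuntimeError(
            f"negative selection did not converge in {sel.max_passes} passes "
            f"({len(bad)} windows above {sel.threshold}); raise the threshold "
            "or max_passes"
        )


# ---------------------------------------------------------------------------
# Genome generation


def _strands(config: SyntheticConfig, rng: np.random.Generator) -> list[str]:
    sa = config.strand_assignment
    if isinstance(sa, str):
        if set(sa) - set("+-"):
            raise ValueError("strand pattern may contain only '+' and '-'")
        return [sa[i % len(sa)] for i in range(config.n_genes)]
    return ["+" if rng.random() < sa else "-" for _ in range(config.n_genes)]


def _gap_class(left: Optional[str], right: Optional[str]) -> str:
    if left is None:
        return OTHER if right == "+" else CONVERGENT
    if right is None:
        return OTHER if left == "-" else CONVERGENT
    return CONVERGENT if (left == "+" and right == "-") else OTHER


def generate_genome(
    config: SyntheticConfig,
) -> tuple[dict[str, str], list[Gene], SyntheticTruth]:
    """Generate one labeled genome.

    Returns the genome (chrom -> sequence), the gene annotation, and the
    ground truth (region classes keyed by the same ``chrom:start-end`` ids
    that :func:`regionks.regions.classify_intergenic` assigns, target
    labels, and planted site coordinates).
    """
    rng = np.random.default_rng(config.rng_seed)
    base_src = config.base_composition or iid_markov([0.25] * 4)
    orf_src = config.orf_source or base_src
    n = config.n_genes
    if n < 1:
        raise ValueError("need at least one gene")

    glo, ghi = config.gene_length_range
    ilo, ihi = config.intergenic_length_range
    gene_lens = rng.integers(glo, ghi + 1, size=n)
    gap_lens = rng.integers(ilo, ihi + 1, size=n + 1)
    strands = _strands(config, rng)

    gap_seqs = [list(sample_sequence(base_src, int(L), rng)) for L in gap_lens]
    gene_seqs = [sample_sequence(orf_src, int(L), rng) for L in gene_lens]

    # gap i sits between gene i-1 and gene i
    flanks = [
        (strands[i - 1] if i > 0 else None, strands[i] if i < n else None)
        for i in range(n + 1)
    ]
    gap_classes = [_gap_class(l, r) for l, r in flanks]

    # choose target gaps among the 'other' class with room for the scanner
    F = required_length(config.motif)
    eligible = [
        i
        for i, c in enumerate(gap_classes)
        if c == OTHER and gap_lens[i] >= F
    ]
    if config.n_target_regions > len(eligible):
        raise ValueError(
            f"requested {config.n_target_regions} target regions but only "
            f"{len(eligible)} eligible other-intergenic gaps were generated"
        )
    target_gaps = sorted(
        rng.choice(eligible, size=config.n_target_regions, replace=False).tolist()
    )

    lo_s, hi_s = config.sites_per_target
    site_records: list[tuple[int, int, int, str, str]] = []  # gap, start, end, strand, seq
    protected: dict[int, list[tuple[int, int]]] = {}
    for gi in target_gaps:
        k = int(rng.integers(lo_s, hi_s + 1))
        emitted = []
        for _ in range(k):
            s = _emit_site(config.motif, config.site_strength, base_src, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            emitted.append((s, strand))
        placed = _place_sites(
            gap_seqs[gi], [s if st == "+" else reverse_complement(s) for s, st in emitted], rng
        )
        protected[gi] = placed
        for (b, e), (s, st) in zip(placed, emitted):
            site_records.append((gi, b, e, st, s))

    sel = config.negative_selection
    if sel.on:
        for gi in range(n + 1):
            if gap_lens[gi] < F:
                continue
            if gi in target_gaps:
                if sel.deplete_targets:
                    _deplete(
                        gap_seqs[gi], config.motif, sel, base_src,
                        protected.get(gi, []), rng,
                    )
            else:
                _deplete(gap_seqs[gi], config.motif, sel, base_src, [], rng)

    # assemble
    chrom = config.chrom_name
    parts = []
    pos = 0
    gap_bounds: list[tuple[int, int]] = []
    genes: list[Gene] = []
    for i in range(n + 1):
        gseq = "".join(gap_seqs[i])
        gap_bounds.append((pos, pos + len(gseq)))
        parts.append(gseq)
        pos += len(gseq)
        if i < n:
            genes.append(
                Gene(
                    gene_id=f"g{i + 1:04d}",
                    chrom=chrom,
                    start=pos,
                    end=pos + int(gene_lens[i]),
                    strand=strands[i],
                )
            )
            parts.append(gene_seqs[i])
            pos += int(gene_lens[i])
    genome = {chrom: "".join(parts)}

    region_ids = [f"{chrom}:{b}-{e}" for b, e in gap_bounds]
    truth = SyntheticTruth(
        region_classes={
            rid: cls for rid, cls in zip(region_ids, gap_classes)
        },
        target_region_ids=[region_ids[i] for i in target_gaps],
        sites=[
            PlantedSite(
                region_id=region_ids[gi],
                chrom=chrom,
                start=gap_bounds[gi][0] + b,
                end=gap_bounds[gi][0] + e,
                strand=st,
                seq=s,
            )
            for gi, b, e, st, s in site_records
        ],
    )
    return genome, genes, truth


# ---------------------------------------------------------------------------
# Presets and evaluation-ready bundles


def _sigma70_model(strength: float) -> PromoterModel:
    return PromoterModel(
        pswm_minus35=pswm_from_consensus("TTGACA", strength, name="minus35"),
        extension=pswm_from_consensus("TG", strength, name="ext_minus10"),
        pswm_minus10=pswm_from_consensus("TATAAT", strength, name="minus10"),
        spacer_weights={15: -1.5, 16: -0.5, 17: 0.0, 18: -0.5, 19: -1.5},
        name="sigma70",
    )


def preset_config(preset: str, rng_seed: int = 0, **overrides) -> SyntheticConfig:
    """Build the configuration for one of the named benchmark presets."""
    at_rich = iid_markov([0.27, 0.23, 0.23, 0.27])  # intergenic-like (GC 46%)
    coding = iid_markov([0.24, 0.26, 0.26, 0.24])  # ORF-like (GC 52%)
    if preset == "crp_like":
        cfg = SyntheticConfig(
            n_genes=260,
            n_target_regions=100,
            sites_per_target=(2, 4),
            site_strength=0.95,
            motif=pswm_from_consensus("AAATGTGATCTAGATCACATTT", 0.95, name="crp"),
            negative_selection=NegativeSelection(on=False),
            base_composition=at_rich,
            orf_source=coding,
            rng_seed=rng_seed,
        )
    elif preset == "fnr_like":
        cfg = SyntheticConfig(
            n_genes=260,
            n_target_regions=60,
            sites_per_target=(1, 2),
            site_strength=0.85,
            motif=pswm_from_consensus("TTGATNNNNATCAA", 0.85, name="fnr"),
            negative_selection=NegativeSelection(on=False),
            base_composition=at_rich,
            orf_source=coding,
            rng_seed=rng_seed,
        )
    elif preset == "sigma70_like":
        strength = 0.65
        cfg = SyntheticConfig(
            n_genes=520,
            intergenic_length_range=(180, 380),
            n_target_regions=200,
            sites_per_target=(3, 5),
            site_strength=strength,
            motif=_sigma70_model(strength),
            negative_selection=NegativeSelection(
                on=True, threshold=-14.0, max_passes=40
            ),
            base_composition=at_rich,
            orf_source=coding,
            rng_seed=rng_seed,
        )
    elif preset == "background_contrast":
        # Weak, sparse targets and strongly GC-shifted ORF negatives: the
        # regime in which the choice of background distribution matters.
        # ORF negatives score so low that their D is ~0 under either
        # background, while the positives' D gains the depleted high-score
        # band only under the convergent background.  The scoring model is
        # the same sigma70 composite as sigma70_like; only the planted
        # sites are emitted more weakly.
        cfg = SyntheticConfig(
            n_genes=800,
            intergenic_length_range=(180, 380),
            n_target_regions=300,
            sites_per_target=(1, 2),
            site_strength=0.55,
            motif=_sigma70_model(0.65),
            negative_selection=NegativeSelection(
                on=True, threshold=-14.0, max_passes=60
            ),
            base_composition=at_rich,
            orf_source=iid_markov([0.21, 0.29, 0.29, 0.21]),  # GC 58%
            rng_seed=rng_seed,
        )
    else:
        raise ValueError(
            f"unknown preset {preset!r}; choose from crp_like, fnr_like, "
            "sigma70_like, background_contrast"
        )
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class Bundle:
    """Everything needed to run and score one benchmark."""

    preset: str
    config: SyntheticConfig
    genome: dict[str, str]
    genes: list[Gene]
    truth: SyntheticTruth
    regions: list[GenomicRegion]
    positives: list[GenomicRegion]
    negatives: list[GenomicRegion]
    background_convergent: BackgroundDistribution
    background_randomized: BackgroundDistribution
    scorer: Scorer
    site_scores: np.ndarray
    strands: str = "both"


def _score_planted_site(
    scorer: Scorer,
    site: PlantedSite,
    genome: dict[str, str],
    base_src: MarkovModel,
    rng: np.random.Generator,
) -> float:
    """Score a planted site in its genomic context (on its own strand);
    composite scorers need the maximal footprint, so the site is read with
    trailing context and padded with source sequence if it runs off the
    chromosome."""
    if isinstance(scorer, PSWM):
        return score_window(scorer, site.seq)
    F = scorer.max_footprint
    chrom_seq = genome[site.chrom]
    if site.strand == "+":
        window = chrom_seq[site.start : site.start + F]
    else:
        window = reverse_complement(chrom_seq[max(0, site.end - F) : site.end])
    if len(window) < F:
        window = window + sample_sequence(base_src, F - len(window), rng)
    return score_promoter(scorer, window, 0)


def benchmark_suite(
    preset: str, rng_seed: int = 0, config: Optional[SyntheticConfig] = None
) -> Bundle:
    """Generate a deterministic, evaluation-ready benchmark bundle.

    The bundle holds the classified regions, the positive set (target
    regions), length-matched ORF-interior putative negatives, both
    background distributions (convergent intergenic and trinucleotide-
    preserving randomized), and the training-site scores for the Max
    baseline threshold.
    """
    cfg = config if config is not None else preset_config(preset, rng_seed)
    genome, genes, truth = generate_genome(cfg)
    regions = classify_intergenic(genes, genome)
    by_id = {r.region_id: r for r in regions}
    positives = [by_id[rid] for rid in truth.target_region_ids]

    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 1]).generate_state(1)[0] % (2**31))
    negatives = sample_orf_interior(
        genes, genome, [len(r) for r in positives], margin=50, rng_seed=rng
    )

    scorer = cfg.motif
    convergent = [r for r in regions if r.region_class == CONVERGENT]
    bg_conv = build_background(
        convergent, scorer, strands="both", source="convergent"
    )

    intergenic_seqs = [r.seq for r in regions]
    markov = fit_markov(intergenic_seqs, order=2)
    rand_seqs = sample_randomized(markov, [len(s) for s in intergenic_seqs], rng)
    bg_rand = build_background(
        rand_seqs, scorer, strands="both", source="randomized"
    )

    base_src = cfg.base_composition or iid_markov([0.25] * 4)
    site_scores = np.array(
        [
            _score_planted_site(scorer, s, genome, base_src, rng)
            for s in truth.sites
        ]
    )
    return Bundle(
        preset=preset,
        config=cfg,
        genome=genome,
        genes=genes,
        truth=truth,
        regions=regions,
        positives=positives,
        negatives=negatives,
        background_convergent=bg_conv,
        background_randomized=bg_rand,
        scorer=scorer,
        site_scores=site_scores,
    )


PRESETS = ("crp_like", "fnr_like", "sigma70_like", "background_contrast")
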