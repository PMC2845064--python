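"""Forward-in-time mutation-drift simulator for genomic-selection benchmarks.

A diploid population of effective size ``Ne`` mates at random for ``n_generations``
discrete generations to reach mutation-drift balance, building up linkage
disequilibrium between markers and QTL.  The genome is ``n_chromosomes``
chromosomes of ``chrom_length_cM`` each, carrying equidistant marker loci and
QTL at marker-bracket midpoints.  Mutation follows an infinite-alleles scheme:
every mutation event creates a new allele label at its locus, and loci are
collapsed to biallelic SNPs afterwards by promoting the mutation lineage with
the highest minor allele frequency to "allele 1" and merging everything else
(including the ancestral allele) into "allele 0".

Two benchmark scenarios are provided: ``SimScenario.data1()`` with 101 markers
per chromosome (1010 genome-wide, a QTL in the middle of every marker bracket)
and ``SimScenario.data2()`` with 1010 markers per chromosome (10100 genome-wide,
a QTL in the middle of every 10th bracket).  Both carry 1000 QTL in total.

The training generation (n = ``n_training``) receives phenotypes
``y = TBV + N(0, residual_variance)``; the following candidate generation
(n = ``n_candidates``) receives genotypes and true breeding values only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import GenotypeMatrix, MarkerMap, PhenotypeTable
from ._popsim_kernels import make_gametes, genotype_codes

__all__ = [
    "SimScenario",
    "HaplotypePopulation",
    "QtlTruth",
    "SimReplicate",
    "build_map",
    "meiosis",
    "run_history",
    "collapse_to_biallelic",
    "assign_qtl_effects",
    "generate_replicate",
]


@dataclass(frozen=True)
class SimScenario:
    """Parameters of the simulated population, genome and trait."""

    n_chromosomes: int = 10
    chrom_length_cM: float = 100.0
    markers_per_chrom: int = 101
    qtl_per_chrom: int = 100
    ne: int = 100
    n_generations: int = 1000
    marker_mutation_rate: float = 2.5e-3
    qtl_mutation_rate: float = 2.5e-5
    gamma_shape: float = 1.66
    gamma_scale: float = 0.4
    residual_variance: float = 1.0
    n_training: int = 1000
    n_candidates: int = 1000

    def __post_init__(self):
        for name in ("n_chromosomes", "markers_per_chrom", "qtl_per_chrom", "ne",
                     "n_training", "n_candidates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        for name in ("marker_mutation_rate", "qtl_mutation_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.chrom_length_cM < 0:
            raise ValueError("chrom_length_cM must be >= 0")
        for name in ("gamma_shape", "gamma_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.residual_variance < 0:
            raise ValueError("residual_variance must be >= 0")

    @classmethod
    def data1(cls, **overrides) -> "SimScenario":
        """Sparse-marker scenario: 1010 markers genome-wide."""
        return cls(**{"markers_per_chrom": 101, **overrides})

    @classmethod
    def data2(cls, **overrides) -> "SimScenario":
        """Dense-marker scenario: 10100 markers genome-wide."""
        return cls(**{"markers_per_chrom": 1010, **overrides})

    def with_overrides(self, **overrides) -> "SimScenario":
        return replace(self, **overrides)


@dataclass
class HaplotypePopulation:
    """Diploid population in the multi-allelic (pre-collapse) representation.

    ``haplotypes[i, h, l]`` is the allele label of haplotype ``h`` of
    individual ``i`` at locus ``l``: 0 for the ancestral allele, ``k >= 1``
    for the ``k``-th mutation event registered at that locus.
    ``mutation_counts[l]`` is the number of registered events, so labels never
    exceed it; lower labels are earlier events.
    """

    haplotypes: np.ndarray  # (n, 2, L) int32
    mutation_counts: np.ndarray  # (L,) int64
    marker_map: MarkerMap
    scenario: SimScenario

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]


@dataclass
class QtlTruth:
    """Per-QTL ground truth after biallelic collapse on the training set."""

    ids: list
    chromosome: np.ndarray
    position_cM: np.ndarray
    effect: np.ndarray       # signed allele-substitution effect (0 if monomorphic)
    polymorphic: np.ndarray  # bool


@dataclass
class SimReplicate:
    """One simulated training + candidate data set with full QTL truth."""

    marker_map: MarkerMap        # full map (markers and QTL)
    training: tuple              # (GenotypeMatrix, PhenotypeTable)
    candidates: tuple            # (GenotypeMatrix, tbv ndarray)
    training_tbv: np.ndarray
    training_qtl_dosage: np.ndarray   # (n_train, n_qtl) int8 signed codes
    candidate_qtl_dosage: np.ndarray  # (n_cand, n_qtl) int8 signed codes
    qtl_truth: QtlTruth
    realized_h2: float


# ---------------------------------------------------------------------------
# genetic map


def build_map(scenario: SimScenario) -> MarkerMap:
    """Lay out equidistant markers and bracket-midpoint QTL on every chromosome.

    Markers span ``[0, chrom_length_cM]`` inclusive of both ends.  QTL sit at
    the midpoints of marker brackets taken every ``stride`` brackets starting
    from the first, where ``stride = n_brackets // qtl_per_chrom`` (1 for the
    sparse scenario, 10 for the dense one).
    """
    n_brackets = scenario.markers_per_chrom - 1
    stride = max(1, n_brackets // scenario.qtl_per_chrom)
    if (n_brackets - 1) // stride + 1 < scenario.qtl_per_chrom:
        raise ValueError("not enough marker brackets for the requested QTL count")
    marker_pos = np.linspace(0.0, scenario.chrom_length_cM, scenario.markers_per_chrom)
    qtl_brackets = np.arange(scenario.qtl_per_chrom) * stride
    qtl_pos = (marker_pos[qtl_brackets] + marker_pos[qtl_brackets + 1]) / 2.0

    ids, chrom, pos, cls = [], [], [], []
    for c in range(1, scenario.n_chromosomes + 1):
        merged = np.concatenate([marker_pos, qtl_pos])
        classes = np.array(["marker"] * len(marker_pos) + ["qtl"] * len(qtl_pos), dtype=object)
        names = np.array(
            [f"M{c}_{i + 1}" for i in range(len(marker_pos))]
            + [f"Q{c}_{i + 1}" for i in range(len(qtl_pos))],
            dtype=object,
        )
        order = np.argsort(merged, kind="stable")
        ids.extend(names[order])
        chrom.extend([c] * len(merged))
        pos.extend(merged[order])
        cls.extend(classes[order])
    return MarkerMap(ids=ids, chromosome=np.array(chrom),
                     position_cM=np.array(pos), locus_class=np.array(cls, dtype=object))


def _map_arrays(mp: MarkerMap):
    """Locus positions, chromosome bounds and class index arrays for kernels."""
    bounds = np.concatenate([[0], np.cumsum(np.bincount(mp.chromosome)[1:])]).astype(np.int64)
    marker_idx = np.flatnonzero(mp.locus_class == "marker").astype(np.int64)
    qtl_idx = np.flatnonzero(mp.locus_class == "qtl").astype(np.int64)
    return mp.position_cM.astype(np.float64), bounds, marker_idx, qtl_idx


# ---------------------------------------------------------------------------
# meiosis and generation advance


def meiosis(parent_haps: np.ndarray, mp: MarkerMap, scenario: SimScenario,
            rng: np.random.Generator, mutation_counts: np.ndarray | None = None):
    """Produce one gamete from a parental haplotype pair.

    Crossover counts per chromosome are Poisson with mean equal to the map
    length in Morgans, positions uniform (Haldane).  The gamete then mutates:
    each locus independently with its class-specific rate, replacing the allele
    by a freshly registered label.  If ``mutation_counts`` is given it is
    updated in place and used to assign labels; otherwise labels start above
    the parent's maximum.
    """
    locus_pos, bounds, marker_idx, qtl_idx = _map_arrays(mp)
    L = mp.n_loci
    C = scenario.n_chromosomes
    coin = rng.integers(0, 2, size=(1, C)).astype(np.int8)
    n_xo = rng.poisson(scenario.chrom_length_cM / 100.0, size=(1, C)).astype(np.int64)
    xo_pos = rng.random(int(n_xo.sum())) * scenario.chrom_length_cM
    xo_off = np.concatenate([[0], np.cumsum(n_xo.ravel())]).astype(np.int64)
    out = np.empty((1, L), dtype=np.int32)
    make_gametes(parent_haps[None, ...].astype(np.int32), np.zeros(1, dtype=np.int64),
                 coin, n_xo, xo_pos, xo_off, locus_pos, bounds, out)
    gamete = out[0]
    if mutation_counts is None:
        mutation_counts = np.zeros(L, dtype=np.int64)
        mutation_counts[:] = parent_haps.max(axis=0)
    for idx, rate in ((marker_idx, scenario.marker_mutation_rate),
                      (qtl_idx, scenario.qtl_mutation_rate)):
        hits = idx[rng.random(idx.size) < rate]
        for l in hits:
            mutation_counts[l] += 1
            gamete[l] = mutation_counts[l]
    return gamete


def _advance(haps: np.ndarray, mutation_counts: np.ndarray, n_offspring: int,
             locus_pos, bounds, marker_idx, qtl_idx, scenario: SimScenario,
             rng: np.random.Generator) -> np.ndarray:
    """One generation of random mating: two distinct parents per offspring."""
    P, _, L = haps.shape
    C = scenario.n_chromosomes
    G = 2 * n_offspring

    p1 = rng.integers(0, P, n_offspring)
    p2 = rng.integers(0, P - 1, n_offspring) if P > 1 else np.zeros(n_offspring, dtype=np.int64)
    if P > 1:
        p2 = p2 + (p2 >= p1)
    parent_ids = np.empty(G, dtype=np.int64)
    parent_ids[0::2] = p1
    parent_ids[1::2] = p2

    coin = rng.integers(0, 2, size=(G, C)).astype(np.int8)
    n_xo = rng.poisson(scenario.chrom_length_cM / 100.0, size=(G, C)).astype(np.int64)
    xo_off = np.concatenate([[0], np.cumsum(n_xo.ravel())]).astype(np.int64)
    xo_pos = rng.random(int(xo_off[-1])) * scenario.chrom_length_cM

    gametes = np.empty((G, L), dtype=np.int32)
    make_gametes(haps, parent_ids, coin, n_xo, xo_pos, xo_off, locus_pos, bounds, gametes)

    for idx, rate in ((marker_idx, scenario.marker_mutation_rate),
                      (qtl_idx, scenario.qtl_mutation_rate)):
        if idx.size == 0 or rate == 0:
            continue
        counts = rng.binomial(idx.size, rate, size=G)
        total = int(counts.sum())
        if total == 0:
            continue
        gam_of_event = np.repeat(np.arange(G), counts)
        loc_of_event = idx[rng.integers(0, idx.size, total)]
        order = np.lexsort((gam_of_event, loc_of_event))
        loc_sorted = loc_of_event[order]
        gam_sorted = gam_of_event[order]
        # rank of each event within its locus group, in event order
        first = np.concatenate([[True], loc_sorted[1:] != loc_sorted[:-1]])
        group_start = np.flatnonzero(first)
        rank = np.arange(total) - np.repeat(group_start, np.diff(np.append(group_start, total)))
        labels = mutation_counts[loc_sorted] + rank + 1
        gametes[gam_sorted, loc_sorted] = labels.astype(np.int32)
        np.add.at(mutation_counts, loc_sorted, 1)

    return gametes.reshape(n_offspring, 2, L)


def run_history(scenario: SimScenario, seed) -> HaplotypePopulation:
    """Evolve the historical population for ``n_generations`` and return it.

    The founder population is fully monomorphic (all-ancestral alleles); the
    long neutral history takes the population to mutation-drift balance.
    """
    rng = _as_generator(seed)
    mp = build_map(scenario)
    locus_pos, bounds, marker_idx, qtl_idx = _map_arrays(mp)
    L = mp.n_loci
    haps = np.zeros((scenario.ne, 2, L), dtype=np.int32)
    mutation_counts = np.zeros(L, dtype=np.int64)
    for _ in range(scenario.n_generations):
        haps = _advance(haps, mutation_counts, scenario.ne,
                        locus_pos, bounds, marker_idx, qtl_idx, scenario, rng)
    return HaplotypePopulation(haplotypes=haps, mutation_counts=mutation_counts,
                               marker_map=mp, scenario=scenario)


# ---------------------------------------------------------------------------
# biallelic collapse and QTL effects


def choose_visible_alleles(pop: HaplotypePopulation) -> np.ndarray:
    """Pick, per locus, the mutation lineage promoted to SNP allele 1.

    Among registered mutation lineages the one with the highest minor allele
    frequency in ``pop`` wins; ties break toward the earliest event (lowest
    label).  Returns an array of chosen labels, 0 where no mutation was ever
    registered.
    """
    n2 = 2 * pop.n_individuals
    L = pop.haplotypes.shape[2]
    chosen = np.zeros(L, dtype=np.int32)
    flat = pop.haplotypes.reshape(n2, L)
    for l in np.flatnonzero(pop.mutation_counts > 0):
        counts = np.bincount(flat[:, l], minlength=int(pop.mutation_counts[l]) + 1)
        freq = counts[1:] / n2
        maf = np.minimum(freq, 1.0 - freq)
        chosen[l] = 1 + int(np.argmax(maf))  # argmax takes the first (earliest) on ties
    return chosen


def collapse_to_biallelic(pop: HaplotypePopulation, chosen: np.ndarray | None = None):
    """Collapse marker loci to biallelic SNPs and emit signed genotype codes.

    Returns ``(chosen, GenotypeMatrix)`` over the marker loci.  Loci with no
    surviving mutation come out monomorphic (all ``-1``).
    """
    if chosen is None:
        chosen = choose_visible_alleles(pop)
    _, _, marker_idx, _ = _map_arrays(pop.marker_map)
    codes = np.empty((pop.n_individuals, marker_idx.size), dtype=np.int8)
    genotype_codes(pop.haplotypes, chosen, marker_idx, codes)
    ids = [pop.marker_map.ids[i] for i in marker_idx]
    gm = GenotypeMatrix(
        individuals=[f"ind{k + 1}" for k in range(pop.n_individuals)],
        snp_ids=ids, codes=codes)
    return chosen, gm


def assign_qtl_effects(pop: HaplotypePopulation, scenario: SimScenario,
                       rng: np.random.Generator,
                       chosen: np.ndarray | None = None) -> QtlTruth:
    """Draw allele-substitution effects for the polymorphic QTL.

    Effect magnitudes are Gamma(``gamma_shape``, ``gamma_scale``) and signs are
    +/- with equal probability; QTL that are monomorphic after the collapse get
    effect 0.  One draw is consumed per QTL locus regardless of polymorphism so
    the effect of a given QTL does not depend on the state of the others.
    """
    if chosen is None:
        chosen = choose_visible_alleles(pop)
    _, _, _, qtl_idx = _map_arrays(pop.marker_map)
    n2 = 2 * pop.n_individuals
    flat = pop.haplotypes.reshape(n2, -1)
    magnitude = rng.gamma(scenario.gamma_shape, scenario.gamma_scale, size=qtl_idx.size)
    sign = np.where(rng.random(qtl_idx.size) < 0.5, 1.0, -1.0)
    count1 = (flat[:, qtl_idx] == chosen[qtl_idx]).sum(axis=0)
    polymorphic = (count1 > 0) & (count1 < n2)
    effect = np.where(polymorphic, magnitude * sign, 0.0)
    return QtlTruth(
        ids=[pop.marker_map.ids[i] for i in qtl_idx],
        chromosome=pop.marker_map.chromosome[qtl_idx],
        position_cM=pop.marker_map.position_cM[qtl_idx],
        effect=effect,
        polymorphic=polymorphic,
    )


# ---------------------------------------------------------------------------
# replicate generation


def _as_generator(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_replicate(scenario: SimScenario, seed) -> SimReplicate:
    """Simulate one full training + candidate replicate.

    The master seed drives independent named substreams (history, the two
    expansion generations, QTL effects, residuals), so e.g. the residual draws
    do not perturb the genotypes.  The biallelic collapse is computed once on
    the training generation and reused unchanged for the candidates.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_hist, s_train, s_cand, s_eff, s_res = ss.spawn(5)

    pop1000 = run_history(scenario, np.random.default_rng(s_hist))
    mp = pop1000.marker_map
    locus_pos, bounds, marker_idx, qtl_idx = _map_arrays(mp)

    mutation_counts = pop1000.mutation_counts
    haps_train = _advance(pop1000.haplotypes, mutation_counts, scenario.n_training,
                          locus_pos, bounds, marker_idx, qtl_idx, scenario,
                          np.random.default_rng(s_train))
    train = HaplotypePopulation(haps_train, mutation_counts, mp, scenario)
    haps_cand = _advance(haps_train, mutation_counts, scenario.n_candidates,
                         locus_pos, bounds, marker_idx, qtl_idx, scenario,
                         np.random.default_rng(s_cand))
    cand = HaplotypePopulation(haps_cand, mutation_counts, mp, scenario)

    chosen = choose_visible_alleles(train)
    _, gm_train = collapse_to_biallelic(train, chosen)
    _, gm_cand = collapse_to_biallelic(cand, chosen)
    gm_cand = GenotypeMatrix(
        individuals=[f"cand{k + 1}" for k in range(scenario.n_candidates)],
        snp_ids=gm_cand.snp_ids, codes=gm_cand.codes)

    truth = assign_qtl_effects(train, scenario, np.random.default_rng(s_eff), chosen)

    qtl_train = np.empty((scenario.n_training, qtl_idx.size), dtype=np.int8)
    genotype_codes(haps_train, chosen, qtl_idx, qtl_train)
    qtl_cand = np.empty((scenario.n_candidates, qtl_idx.size), dtype=np.int8)
    genotype_codes(haps_cand, chosen, qtl_idx, qtl_cand)

    tbv_train = qtl_train.astype(np.float64) @ truth.effect
    tbv_cand = qtl_cand.astype(np.float64) @ truth.effect

    rng_res = np.random.default_rng(s_res)
    noise = rng_res.normal(0.0, np.sqrt(scenario.residual_variance), scenario.n_training)
    y = tbv_train + noise

    pt = PhenotypeTable(individuals=list(gm_train.individuals), y=y,
                        X=np.ones((scenario.n_training, 1)))

    var_tbv = float(np.var(tbv_train, ddof=1))
    h2 = var_tbv / (var_tbv + scenario.residual_variance)

    return SimReplicate(
        marker_map=mp,
        training=(gm_train, pt),
        candidates=(gm_cand, tbv_cand),
        training_tbv=tbv_train,
        training_qtl_dosage=qtl_train,
        candidate_qtl_dosage=qtl_cand,
        qtl_truth=truth,
        realized_h2=h2,
    )
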