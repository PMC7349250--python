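"""Forward-time diploid Wright–Fisher simulator with known truth.

Discrete, non-overlapping generations of N diploids; each offspring
draws two parents uniformly at random (selfing allowed). Per gamete,
recombination places Poisson(rec_per_bp × L) crossovers uniformly along
each chromosome (chromosomes assort independently), and mutation adds
Poisson(mu_per_bp × L) new infinite-sites variants at uniform positions
(collisions redrawn), so every variant stays biallelic. Runs start from
mutation-free founders and burn in for 10 × N generations by default to
approach mutation–drift equilibrium before the configured size schedule.

The final generation is sampled without replacement and exported as a
genotype matrix (with optional phased VCF), together with a truth record:
the realised size per generation, per-chromosome variant counts, the
sampled true haplotypes and population assignments. A fixed seed gives
byte-identical output.

An optional terminal split partitions the population into equal
subpopulations with no migration for the last ``split_generations``
generations — the minimal scenario for weak differentiation among
recently separated herds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import GenotypeMatrix, PopulationMap, VariantRecord, write_popmap, write_vcf

logger = logging.getLogger("gbspopgen")

MAX_DIPLOIDS = 500
MAX_SCHEDULE_GENERATIONS = 500
MAX_TOTAL_BP = 10_000_000


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Scenario specification for :func:`simulate`.

    ne_schedule
        Ordered (n_generations, diploid size) phases run after burn-in.
    chromosomes
        (label, length_bp) pairs.
    mu_per_bp, rec_per_bp
        Per-generation per-bp mutation and recombination rates.
    n_sampled
        Diploids sampled (without replacement) from the final generation.
    seed
        Seed for the single pseudo-random stream of the run.
    split_generations, n_subpops
        If ``split_generations > 0`` the population is partitioned into
        ``n_subpops`` equal groups, closed to migration, for that many
        final generations.
    burn_in_factor
        Burn-in length as a multiple of the initial size (default 10).
    missing_rate
        Uniform random genotype missingness applied on export.
    min_export_maf
        Ascertainment floor: variants with sample MAF below this are not
        exported (0 = export every polymorphic site). Emulates data sets
        distributed after marker filtering.
    """

    ne_schedule: list[tuple[int, int]]
    chromosomes: list[tuple[str, int]]
    mu_per_bp: float
    rec_per_bp: float
    n_sampled: int
    seed: int
    split_generations: int = 0
    n_subpops: int = 1
    burn_in_factor: int = 10
    missing_rate: float = 0.0
    min_export_maf: float = 0.0

    def validate(self) -> None:
        if not self.ne_schedule or not self.chromosomes:
            raise SimulationError("schedule and chromosomes must be non-empty")
        sizes = [n for _, n in self.ne_schedule]
        gens = sum(g for g, _ in self.ne_schedule)
        total_bp = sum(length for _, length in self.chromosomes)
        if min(sizes) < 2:
            raise SimulationError("population sizes must be >= 2")
        if max(sizes) > MAX_DIPLOIDS:
            raise SimulationError(f"population size > {MAX_DIPLOIDS} exceeds desk scale")
        if gens > MAX_SCHEDULE_GENERATIONS:
            raise SimulationError(
                f"schedule of {gens} generations exceeds desk scale "
                f"({MAX_SCHEDULE_GENERATIONS})"
            )
        if total_bp > MAX_TOTAL_BP:
            raise SimulationError(f"genome of {total_bp} bp exceeds desk scale")
        if self.mu_per_bp < 0 or self.rec_per_bp < 0:
            raise SimulationError("rates must be >= 0")
        if self.n_sampled > sizes[-1]:
            raise SimulationError("cannot sample more diploids than the final size")
        if self.n_subpops > 1 and self.split_generations > 0:
            if sizes[-1] % self.n_subpops:
                raise SimulationError("final size must divide evenly into subpopulations")
        if not 0 <= self.missing_rate < 1:
            raise SimulationError("missing_rate must be in [0, 1)")


@dataclass
class TruthRecord:
    """Realised truth of one simulation run."""

    ne_per_generation: list[int]
    variants_per_chrom: dict[str, int]
    sample_ids: list[str]
    sample_pops: list[str]
    haplotypes: np.ndarray  # (n_sampled, 2, n_variants) in export order
    positions: np.ndarray
    chroms: np.ndarray

    def to_text(self) -> str:
        lines = ["# gbspopgen simulation truth record"]
        lines.append("n_generations\t%d" % len(self.ne_per_generation))
        lines.append(
            "ne_schedule\t" + ",".join(str(n) for n in self.ne_per_generation)
        )
        for chrom, n in self.variants_per_chrom.items():
            lines.append(f"variants\t{chrom}\t{n}")
        for sid, pop in zip(self.sample_ids, self.sample_pops):
            lines.append(f"sample\t{sid}\t{pop}")
        return "\n".join(lines) + "\n"


class _Chromosome:
    """Haplotype state for one chromosome: positions plus 2N × S alleles."""

    __slots__ = ("label", "length", "positions", "haps")

    def __init__(self, label: str, length: int, n_haps: int):
        self.label = label
        self.length = length
        self.positions = np.empty(0, dtype=np.int64)
        self.haps = np.zeros((n_haps, 0), dtype=np.int8)


def _next_generation(
    chrom: _Chromosome,
    parent_of_gamete: np.ndarray,
    rng: np.random.Generator,
    rec_per_bp: float,
    mu_per_bp: float,
    taken_positions: set[int],
) -> None:
    """Advance one chromosome a generation, in place.

    ``parent_of_gamete`` maps each of the 2·N_next gametes to a parent
    individual index in the current generation.
    """
    n_gametes = parent_of_gamete.size
    # each gamete starts from one of the parent's two haplotypes
    start = rng.integers(0, 2, size=n_gametes)
    hap_idx = 2 * parent_of_gamete + start

    n_cross = rng.poisson(rec_per_bp * chrom.length, size=n_gametes)
    new = chrom.haps[hap_idx]  # row gather; correct for 0-crossover gametes
    for g in np.flatnonzero(n_cross):
        cuts = np.sort(rng.integers(1, chrom.length + 1, size=n_cross[g]))
        parity = np.searchsorted(cuts, chrom.positions, side="left") % 2
        h0 = chrom.haps[2 * parent_of_gamete[g] + start[g]]
        h1 = chrom.haps[2 * parent_of_gamete[g] + 1 - start[g]]
        new[g] = np.where(parity == 0, h0, h1)

    # batch all new mutations of this generation as appended columns
    n_mut = rng.poisson(mu_per_bp * chrom.length * n_gametes)
    if n_mut:
        mut_pos = np.empty(n_mut, dtype=np.int64)
        filled = 0
        while filled < n_mut:
            cand = rng.integers(1, chrom.length + 1, size=n_mut - filled)
            for p in cand:
                if p not in taken_positions:
                    taken_positions.add(int(p))
                    mut_pos[filled] = p
                    filled += 1
        carriers = rng.integers(0, n_gametes, size=n_mut)
        block = np.zeros((n_gametes, n_mut), dtype=np.int8)
        block[carriers, np.arange(n_mut)] = 1
        chrom.positions = np.concatenate([chrom.positions, mut_pos])
        chrom.haps = np.concatenate([new, block], axis=1)
    else:
        chrom.haps = new

    # prune sites lost or fixed in the whole population
    counts = chrom.haps.sum(axis=0, dtype=np.int64)
    seg = (counts > 0) & (counts < n_gametes)
    if not seg.all():
        lost_or_fixed = np.flatnonzero(~seg)
        for p in chrom.positions[lost_or_fixed]:
            taken_positions.discard(int(p))
        chrom.positions = chrom.positions[seg]
        chrom.haps = chrom.haps[:, seg]


def simulate(
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, TruthRecord, np.ndarray]:
    """Run a Wright–Fisher scenario.

    Returns ``(genotype_matrix, truth, haplotypes)`` where *haplotypes*
    has shape ``(n_sampled, 2, n_variants)`` aligned with the matrix's
    variant order, before any export missingness is applied.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n0 = cfg.ne_schedule[0][1]
    phases = [(cfg.burn_in_factor * n0, n0)] + list(cfg.ne_schedule)
    total_gens = sum(g for g, _ in phases)
    split_at = total_gens - cfg.split_generations  # generation index where split begins

    chroms = [_Chromosome(label, length, 2 * n0) for label, length in cfg.chromosomes]
    taken: list[set[int]] = [set() for _ in chroms]

    pop_of: np.ndarray | None = None
    n_current = n0
    realized: list[int] = []
    gen_counter = 0
    for phase_gens, phase_n in phases:
        for _ in range(phase_gens):
            n_next = phase_n
            if cfg.n_subpops > 1 and gen_counter == split_at:
                # partition the current generation into closed subpopulations
                perm = rng.permutation(n_current)
                pop_of = np.empty(n_current, dtype=int)
                for k in range(cfg.n_subpops):
                    pop_of[perm[k::cfg.n_subpops]] = k
            if pop_of is None:
                parents = rng.integers(0, n_current, size=2 * n_next)
            else:
                # offspring keep subpopulation proportions; parents drawn within
                per = n_next // cfg.n_subpops
                parents = np.empty(2 * n_next, dtype=np.int64)
                new_pop = np.empty(n_next, dtype=int)
                off = 0
                for k in range(cfg.n_subpops):
                    members = np.flatnonzero(pop_of == k)
                    n_off = per + (1 if k < n_next % cfg.n_subpops else 0)
                    draws = members[rng.integers(0, members.size, size=2 * n_off)]
                    parents[2 * off : 2 * (off + n_off)] = draws
                    new_pop[off : off + n_off] = k
                    off += n_off
                pop_of = new_pop
            for chrom, taken_set in zip(chroms, taken):
                _next_generation(
                    chrom, parents, rng, cfg.rec_per_bp, cfg.mu_per_bp, taken_set
                )
            n_current = n_next
            realized.append(n_current)
            gen_counter += 1

    # sample diploids without replacement, stratified over subpopulations
    if pop_of is not None:
        chosen: list[int] = []
        per = cfg.n_sampled // cfg.n_subpops
        for k in range(cfg.n_subpops):
            members = np.flatnonzero(pop_of == k)
            n_take = per + (1 if k < cfg.n_sampled % cfg.n_subpops else 0)
            if n_take > members.size:
                raise SimulationError(
                    f"subpopulation {k} too small to sample {n_take} diploids"
                )
            chosen.extend(rng.choice(members, size=n_take, replace=False).tolist())
        chosen_arr = np.array(chosen)
        sample_pops = [f"pop{pop_of[i] + 1}" for i in chosen_arr]
    else:
        chosen_arr = rng.choice(n_current, size=cfg.n_sampled, replace=False)
        sample_pops = ["pop1"] * cfg.n_sampled

    sample_ids = [f"S{i:03d}" for i in range(cfg.n_sampled)]

    # assemble export: per chromosome, sort by position, drop sample-monomorphic
    hap_blocks = []
    variant_records: list[VariantRecord] = []
    variants_per_chrom: dict[str, int] = {}
    ref_alt = np.array(["A", "C", "G", "T"])
    for chrom in chroms:
        rows = np.empty((cfg.n_sampled * 2, chrom.positions.size), dtype=np.int8)
        rows[0::2] = chrom.haps[2 * chosen_arr]
        rows[1::2] = chrom.haps[2 * chosen_arr + 1]
        counts = rows.sum(axis=0, dtype=np.int64)
        seg = (counts > 0) & (counts < rows.shape[0])
        if cfg.min_export_maf > 0:
            maf = np.minimum(counts, rows.shape[0] - counts) / rows.shape[0]
            seg &= maf >= cfg.min_export_maf
        order = np.argsort(chrom.positions[seg], kind="stable")
        keep = np.flatnonzero(seg)[order]
        hap_blocks.append(rows[:, keep])
        variants_per_chrom[chrom.label] = keep.size
        alleles = rng.integers(0, 4, size=(keep.size, 2))
        alleles[:, 1] = (alleles[:, 0] + 1 + alleles[:, 1] % 3) % 4  # ref != alt
        for p, (ai, aj) in zip(chrom.positions[keep], alleles):
            variant_records.append(
                VariantRecord(chrom.label, int(p), str(ref_alt[ai]), str(ref_alt[aj]))
            )

    if not variant_records:
        logger.warning("simulate: zero polymorphic sites in the sample")
        haps = np.zeros((cfg.n_sampled, 2, 0), dtype=np.int8)
    else:
        flat = np.concatenate(hap_blocks, axis=1)
        haps = flat.reshape(cfg.n_sampled, 2, -1)

    dosage = haps.sum(axis=1, dtype=np.int8)
    if cfg.missing_rate > 0 and dosage.size:
        mask = rng.random(dosage.shape) < cfg.missing_rate
        dosage = np.where(mask, np.int8(-1), dosage)

    gm = GenotypeMatrix(sample_ids, variant_records, dosage)
    truth = TruthRecord(
        ne_per_generation=realized,
        variants_per_chrom=variants_per_chrom,
        sample_ids=sample_ids,
        sample_pops=sample_pops,
        haplotypes=haps,
        positions=gm.positions if variant_records else np.empty(0, dtype=np.int64),
        chroms=gm.chroms if variant_records else np.empty(0, dtype=object),
    )
    logger.info(
        "simulate: %d generations, %d sampled diploids, %d variants",
        total_gens, cfg.n_sampled, gm.n_variants,
    )
    return gm, truth, haps


def make_study_like_fixture(
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[GenotypeMatrix, PopulationMap, TruthRecord]:
    """A small synthetic data set shaped like a GBS herd survey.

    Five subpopulations split one generation ago from one ancestral
    herd of 250 diploids (expected pairwise FST ≈ t/(2·N_sub) ≈ 0.01,
    matching the weak-differentiation regime of herd surveys); 50
    sampled diploids, fifteen 240-kb chromosomes (many independently
    assorting linkage groups keep the multi-locus FST estimate near its
    expectation, as in real multi-chromosome data),
    mutation rate set for >2,000 exported SNPs, and an export MAF floor
    of 0.05 so the fixture is shaped like an already-ascertained GBS
    panel (mean MAF ≈ 0.2, QC re-run retains nearly everything).

    If ``out_dir`` is given, writes ``fixture.vcf`` (phased) and
    ``fixture.popmap.tsv`` there.
    """
    cfg = SimulationConfig(
        ne_schedule=[(10, 250)],
        chromosomes=[(f"chr{i + 1}", 240_000) for i in range(15)],
        mu_per_bp=3.0e-7,
        rec_per_bp=1e-8,
        n_sampled=50,
        seed=seed,
        split_generations=1,
        n_subpops=5,
        min_export_maf=0.05,
    )
    gm, truth, haps = simulate(cfg)
    pm = PopulationMap(dict(zip(truth.sample_ids, truth.sample_pops)))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_vcf(gm, out_dir / "fixture.vcf", haplotypes=haps)
        write_popmap(pm, out_dir / "fixture.popmap.tsv")
        with open(out_dir / "fixture.truth.txt", "w") as fh:
            fh.write(truth.to_text())
    return gm, pm, truth
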