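"""Simulation of neutral samples and selective sweeps of varying softness.

Neutral samples are drawn directly from the coalescent (msprime).  Sweeps
are generated by a rescaled forward Wright-Fisher simulation: the diploid
population of size ``N_e`` is shrunk by a factor ``Q`` to ``N' = N_e/Q``
while per-generation rates are inflated by ``Q``, preserving the
population-scaled parameters ``theta = 4 N_e mu L``, ``rho_pop = 4 N_e r``,
``theta_A = 4 N_e mu_A`` and ``2 N_e s``.  The forward population is founded
from an exact stationary coalescent sample of all ``2 N'`` haplotypes, so no
forward burn-in is required.

Two sweep modes are supported:

* ``de_novo`` - recurrent adaptive mutation at the central site at rate
  ``mu_A = theta_A / (4 N')`` per haplotype per generation; each origin is
  labelled so the number of independent sweeping haplotypes can be counted.
* ``sgv`` - a single adaptive allele is dropped on one haplotype and drifts
  neutrally until it first reaches frequency ``f0`` (rejection sampling on
  the trajectory, which preserves the identity-by-descent structure among
  carriers); selection then begins.  At the onset of selection every carrier
  haplotype receives a distinct origin label, so origins count distinct
  haplotype backgrounds of the standing variant.

Selection is co-dominant with fitnesses ``1 : 1+s : 1+2s`` and is switched
off the first time the adaptive-allele frequency reaches ``PF``; the
population then evolves neutrally for ``T_E * 4 N_e`` generations (rescaled)
before ``n`` haplotypes are sampled without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import msprime
import numpy as np

from hapsweep.haplodata import HaplotypeMatrix, _fractions_to_bp

__all__ = [
    "Demography",
    "SweepModel",
    "SweepSample",
    "SweepLossError",
    "simulate",
    "count_origins",
    "footprint_length",
    "write_ms",
]


#: Cap on the per-generation selection coefficient in the rescaled forward
#: simulation; see _Population.__init__ for how event rates compensate.
S_MAX = 1.0


def _p_establish(s: float) -> float:
    """Branching-process establishment probability of a single copy whose
    offspring number is ~Poisson(1 + s): 1 - q with q = exp((1+s)(q-1)).
    Approaches 2s for small s."""
    q = np.exp(-2 * s)  # starting guess from the small-s limit
    for _ in range(200):
        q_new = np.exp((1 + s) * (q - 1))
        if abs(q_new - q) < 1e-12:
            break
        q = q_new
    return float(1 - q)


class SweepLossError(RuntimeError):
    """The adaptive allele failed to reach its target within the retry budget."""


@dataclass(frozen=True)
class Demography:
    """Neutral demographic history of the sampled population.

    ``model`` is one of ``constant``, ``bottleneck`` or ``admixture``.

    Bottleneck parameters follow the relative-size convention: ``nb`` and
    ``nf`` are population sizes relative to the ancestral size ``ne``, and
    ``tb`` (bottleneck duration) and ``tf`` (time since recovery) are in
    units of ``2 N_ancestral`` generations.  Looking back from the present:
    size ``nf * ne`` for ``tf * 2 ne`` generations, then ``nb * ne`` for
    ``tb * 2 ne`` generations, then ``ne``.

    The admixture model is a user-parameterized template: the sampled
    population is founded ``t_adm * 4 ne`` generations ago by admixture of
    two source populations (sizes ``n1 * ne`` and ``n2 * ne``) with
    proportion ``prop`` drawn from the first source; the sources themselves
    derive from a common ancestral population of size ``ne`` at
    ``t_split * 4 ne`` generations ago.
    """

    model: str = "constant"
    ne: float = 1e6
    nb: float = 0.002
    tb: float = 0.0002
    nf: float = 1.0
    tf: float = 0.0
    n1: float = 1.0
    n2: float = 1.0
    prop: float = 0.5
    t_adm: float = 3.05e-4 / 4  # founding time in 4*ne generations
    t_split: float = 0.05  # source-population split time, 4*ne generations

    def to_msprime(self) -> tuple[msprime.Demography, dict | int]:
        """msprime demography plus the sample specification for it.

        Sizes are expressed as numbers of haploid genomes (2N) so that all
        simulations can run with ``ploidy=1``.
        """
        if self.model == "constant":
            dem = msprime.Demography()
            dem.add_population(name="pop", initial_size=2 * self.ne)
            return dem, {"pop": 0}
        if self.model == "bottleneck":
            dem = msprime.Demography()
            dem.add_population(name="pop", initial_size=2 * self.nf * self.ne)
            t0 = self.tf * 2 * self.ne
            dem.add_population_parameters_change(
                time=t0, initial_size=2 * self.nb * self.ne, population="pop"
            )
            dem.add_population_parameters_change(
                time=t0 + self.tb * 2 * self.ne,
                initial_size=2 * self.ne,
                population="pop",
            )
            return dem, {"pop": 0}
        if self.model == "admixture":
            if not self.t_adm < self.t_split:
                raise ValueError("admixture must postdate the source split")
            dem = msprime.Demography()
            dem.add_population(name="adm", initial_size=2 * self.ne)
            dem.add_population(name="src1", initial_size=2 * self.n1 * self.ne)
            dem.add_population(name="src2", initial_size=2 * self.n2 * self.ne)
            dem.add_population(name="anc", initial_size=2 * self.ne)
            dem.add_admixture(
                time=self.t_adm * 4 * self.ne,
                derived="adm",
                ancestral=["src1", "src2"],
                proportions=[self.prop, 1 - self.prop],
            )
            dem.add_population_split(
                time=self.t_split * 4 * self.ne,
                derived=["src1", "src2"],
                ancestral="anc",
            )
            return dem, {"adm": 0}
        raise ValueError(f"unknown demographic model {self.model!r}")


@dataclass(frozen=True)
class SweepModel:
    """Parameters of one simulated locus.

    Rates are per bp per generation; ``rho_cm_per_bp`` is in cM/bp (1 cM =
    0.01 crossovers).  ``theta_a`` applies in ``de_novo`` mode, ``f0`` in
    ``sgv`` mode.  ``pf`` is the adaptive-allele frequency at which
    selection ceases and ``t_e`` the time since then in units of ``4 N_e``
    generations.  ``rescale_q`` defaults to ``ne / 500`` (forward population
    of 500 diploids).
    """

    demography: Demography = field(default_factory=Demography)
    locus_length: int = 100_000
    mu: float = 1e-9
    rho_cm_per_bp: float = 5e-7
    mode: str = "neutral"
    theta_a: float = 0.0
    f0: float = 0.0
    s: float = 0.0
    pf: float = 1.0
    t_e: float = 0.0
    sample_size: int = 145
    rescale_q: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("neutral", "de_novo", "sgv"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.pf <= 1:
            raise ValueError("pf must be in (0, 1]")
        if not 0 <= self.f0 < 1:
            raise ValueError("f0 must be in [0, 1)")
        if self.s < 0 or self.theta_a < 0 or self.t_e < 0:
            raise ValueError("s, theta_a and t_e must be non-negative")

    @property
    def r_per_bp(self) -> float:
        """Crossover probability per bp per generation."""
        return self.rho_cm_per_bp * 0.01

    @property
    def n_prime(self) -> int:
        """Rescaled diploid population size N' = N_e / Q."""
        q = self.rescale_q if self.rescale_q is not None else self.demography.ne / 500
        n = int(round(self.demography.ne / q))
        if n < 50:
            raise ValueError(f"rescaled population N' = {n} too small")
        return n


@dataclass
class SweepSample:
    """One simulated sample with its adaptive-site annotations."""

    matrix: HaplotypeMatrix
    mode: str
    adaptive_col: int | None
    origin_labels: np.ndarray  # per sampled haplotype, -1 = non-carrier
    final_frequency: float  # population frequency when selection ceased
    locus_length: int

    @property
    def n_carriers(self) -> int:
        return int(np.sum(self.origin_labels >= 0))


def footprint_length(s: float, ne: float, rho: float) -> float:
    """Expected hard-sweep footprint width, s / (ln(N_e s) * rho), in bp.

    ``rho`` is the per-bp recombination probability per generation.  The
    natural log is used, as in the sweep-width literature.  Requires
    ``N_e * s > 1`` so the log is positive.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    if ne * s <= 1:
        raise ValueError("footprint undefined for N_e * s <= 1")
    return s / (np.log(ne * s) * rho)


def count_origins(sample: SweepSample) -> int:
    """Number of distinct adaptive-mutation origins among sampled carriers."""
    if sample.mode == "neutral":
        raise ValueError("origin counts are undefined for neutral samples")
    labels = sample.origin_labels[sample.origin_labels >= 0]
    return int(np.unique(labels).size)


def simulate(
    model: SweepModel,
    seed: int,
    min_snps: int = 0,
    max_restarts: int = 1000,
) -> SweepSample:
    """Simulate one sample under ``model``.

    ``min_snps`` rejects and redraws samples with fewer segregating sites
    (analysis pipelines that need full 400-SNP windows pass 400).
    ``max_restarts`` bounds internal retries after sweep loss and sample
    rejection.
    """
    rng = np.random.default_rng(seed)
    for _ in range(max(1, max_restarts)):
        if model.mode == "neutral":
            sample = _simulate_neutral(model, rng)
        else:
            sample = _simulate_sweep(model, rng, max_restarts)
        if sample.matrix.n_snps >= min_snps:
            return sample
    raise SweepLossError(
        f"no sample with >= {min_snps} SNPs in {max_restarts} attempts"
    )


# ---------------------------------------------------------------------------
# neutral coalescent path


def _msprime_sample(
    model: SweepModel, n_haplotypes: int, rng: np.random.Generator, rescaled: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a stationary sample: (haplotypes x sites matrix, float positions).

    With ``rescaled=True`` the draw founds the forward population: sizes are
    shrunk by Q and per-generation rates inflated by Q, preserving all
    population-scaled parameters.
    """
    if rescaled:
        if model.demography.model != "constant":
            raise ValueError(
                "forward sweep simulation supports the constant demography only"
            )
        q = model.demography.ne / model.n_prime
        dem = msprime.Demography()
        dem.add_population(name="pop", initial_size=2 * model.n_prime)
        r, mu = model.r_per_bp * q, model.mu * q
    else:
        dem, sample_pop = model.demography.to_msprime()
        r, mu = model.r_per_bp, model.mu
    ts = msprime.sim_ancestry(
        samples={"pop" if rescaled else next(iter(sample_pop)): n_haplotypes},
        ploidy=1,
        demography=dem,
        sequence_length=model.locus_length,
        recombination_rate=r,
        discrete_genome=False,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    mts = msprime.sim_mutations(
        ts,
        rate=mu,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    G = mts.genotype_matrix().T.astype(np.int8)  # haplotypes x sites
    pos = np.array([s.position for s in mts.sites()], dtype=float)
    # keep biallelic segregating columns only
    seg = (G.sum(axis=0) > 0) & (G.sum(axis=0) < G.shape[0]) & (G.max(axis=0) <= 1)
    return np.ascontiguousarray(G[:, seg]), pos[seg]


def _simulate_neutral(model: SweepModel, rng: np.random.Generator) -> SweepSample:
    G, pos = _msprime_sample(model, model.sample_size, rng, rescaled=False)
    matrix = HaplotypeMatrix(
        "sim",
        _fractions_to_bp(pos / model.locus_length, model.locus_length),
        G,
    )
    return SweepSample(
        matrix=matrix,
        mode="neutral",
        adaptive_col=None,
        origin_labels=np.full(model.sample_size, -1, dtype=np.int64),
        final_frequency=0.0,
        locus_length=model.locus_length,
    )


def simulate_neutral_alleles(
    model: SweepModel, n_reps: int, seed: int, min_snps: int = 0
):
    """Yield ``n_reps`` neutral allele matrices (haplotypes x sites).

    A batched fast path for calibration runs: replicates share one msprime
    ancestry iterator, which avoids per-replicate simulator setup.  Replicates
    with fewer than ``min_snps`` segregating sites are discarded and
    replaced.  Yields bare int8 matrices; use :func:`simulate` when positions
    and sample bookkeeping are needed.
    """
    if model.mode != "neutral":
        raise ValueError("batched path is for neutral models only")
    rng = np.random.default_rng(seed)
    dem, sample_pop = model.demography.to_msprime()
    produced = 0
    while produced < n_reps:
        batch = min(2 * (n_reps - produced) + 8, 10_000)
        reps = msprime.sim_ancestry(
            samples={next(iter(sample_pop)): model.sample_size},
            ploidy=1,
            demography=dem,
            sequence_length=model.locus_length,
            recombination_rate=model.r_per_bp,
            discrete_genome=False,
            num_replicates=batch,
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
        for ts in reps:
            mts = msprime.sim_mutations(
                ts,
                rate=model.mu,
                model=msprime.BinaryMutationModel(),
                discrete_genome=False,
                random_seed=int(rng.integers(1, 2**31 - 1)),
            )
            if mts.num_sites < min_snps:
                continue
            yield np.ascontiguousarray(mts.genotype_matrix().T.astype(np.int8))
            produced += 1
            if produced >= n_reps:
                break


# ---------------------------------------------------------------------------
# forward Wright-Fisher path


class _Population:
    """Mutable forward-simulation state: 2N' haplotypes over float positions."""

    def __init__(self, H: np.ndarray, pos: np.ndarray, model: SweepModel):
        self.H = H  # (2N', S) int8, positions sorted
        self.pos = pos
        self.model = model
        self.nh = H.shape[0]  # 2N'
        self.adaptive = np.zeros(self.nh, dtype=bool)
        self.origin = np.full(self.nh, -1, dtype=np.int64)
        self.next_label = 0
        q = model.demography.ne / (self.nh // 2)
        self.s_prime = model.s * q
        self.mu_prime = model.mu * q
        self.r_prime = model.r_per_bp * q
        self.mu_a = model.theta_a / (2 * self.nh)  # theta_A / (4 N')
        # Rescaling caps the per-generation selection intensity at S_MAX: a
        # discrete generation cannot represent more than about a doubling of
        # the adaptive allele, so for s' = sQ > S_MAX the sweep runs at
        # selection coefficient S_MAX while all per-generation event rates
        # (recombination, neutral and adaptive mutation) are multiplied by
        # S_MAX / s'.  Events per unit of allele-frequency change — which is
        # what shapes the swept haplotypes — then match the target process.
        self.s_eff = min(self.s_prime, S_MAX) if self.s_prime > 0 else 0.0
        self.sel_factor = self.s_eff / self.s_prime if self.s_prime > 0 else 1.0
        # Adaptive mutation follows a different invariant than recombination:
        # what must be preserved is establishing origins per unit of allele-
        # frequency change, theta_A / x.  Influx x establishment / speed gives
        # mu_a_eff * p_est(s_eff) / s_eff = mu_a * 2, hence:
        if self.s_eff > 0:
            self.mu_a_eff = self.mu_a * 2 * self.s_eff / _p_establish(self.s_eff)
        else:
            self.mu_a_eff = self.mu_a
        self.center = model.locus_length / 2.0
        self._gens_since_prune = 0

    def snapshot(self) -> tuple:
        return (
            self.H.copy(),
            self.pos.copy(),
            self.adaptive.copy(),
            self.origin.copy(),
            self.next_label,
        )

    def restore(self, snap: tuple) -> None:
        self.H, self.pos, self.adaptive, self.origin, self.next_label = (
            snap[0].copy(),
            snap[1].copy(),
            snap[2].copy(),
            snap[3].copy(),
            snap[4],
        )

    def seed_origin(self, rng: np.random.Generator) -> None:
        """Place one adaptive copy on a random haplotype with a fresh label."""
        i = int(rng.integers(self.nh))
        self.adaptive[i] = True
        self.origin[i] = self.next_label
        self.next_label += 1

    def relabel_carriers(self) -> None:
        """Give each current carrier a distinct label (SGV selection onset)."""
        idx = np.flatnonzero(self.adaptive)
        self.origin[idx] = np.arange(idx.size)
        self.next_label = idx.size

    def count(self) -> int:
        return int(self.adaptive.sum())

    def step(
        self,
        rng: np.random.Generator,
        selection: bool,
        adaptive_mutation: bool,
        pf_count: int | None = None,
    ) -> None:
        """Advance one generation of random mating with recombination.

        When ``pf_count`` is given and the new generation would overshoot it,
        excess adaptive children are regenerated from non-adaptive
        transmissions so the crossing generation lands exactly on the target
        count (the forward analogue of conditioning the allele-frequency
        trajectory to stop at PF).
        """
        nh, nd = self.nh, self.nh // 2
        L = float(self.model.locus_length)
        scale = self.sel_factor if selection else 1.0
        g = self.adaptive[0::2].astype(np.float64) + self.adaptive[1::2]
        if selection and self.s_eff > 0 and 0 < g.sum() < 2 * nd:
            w = 1.0 + self.s_eff * g
            parents = rng.choice(nd, size=nh, p=w / w.sum())
        else:
            parents = rng.integers(0, nd, size=nh)

        new_H, new_adaptive, new_origin = self._make_children(rng, parents, scale)

        if adaptive_mutation and self.mu_a > 0:
            hits = np.flatnonzero(
                (~new_adaptive) & (rng.random(nh) < self.mu_a_eff)
            )
            if hits.size:
                new_adaptive[hits] = True
                new_origin[hits] = self.next_label + np.arange(hits.size)
                self.next_label += hits.size

        if pf_count is not None and int(new_adaptive.sum()) > pf_count:
            self._trim_overshoot(
                rng, new_H, new_adaptive, new_origin, g, pf_count, scale
            )

        self.H, self.adaptive, self.origin = new_H, new_adaptive, new_origin

        m = rng.poisson(nh * self.mu_prime * scale * L)
        if m:
            new_pos = rng.uniform(0.0, L, size=m)
            carriers = rng.integers(0, nh, size=m)
            add = np.zeros((nh, m), dtype=np.int8)
            add[carriers, np.arange(m)] = 1
            merged = np.concatenate([self.pos, new_pos])
            order = np.argsort(merged, kind="stable")
            self.pos = merged[order]
            self.H = np.concatenate([self.H, add], axis=1)[:, order]

        self._gens_since_prune += 1
        if self._gens_since_prune >= 8:
            self._prune()

    def _make_children(
        self, rng: np.random.Generator, parents: np.ndarray, scale: float = 1.0
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorized meiosis: one recombinant haplotype per parent index."""
        m = parents.size
        L = float(self.model.locus_length)
        a_idx, b_idx = 2 * parents, 2 * parents + 1
        phase = rng.integers(0, 2, size=m).astype(np.int8)
        k = rng.poisson(self.r_prime * scale * L, size=m)
        tot = int(k.sum())
        S = self.pos.size
        if tot:
            rows = np.repeat(np.arange(m), k)
            bps = rng.uniform(0.0, L, size=tot)
            cols = np.searchsorted(self.pos, bps)
            par = np.zeros((m, S + 1), dtype=np.int8)
            np.add.at(par, (rows, cols), 1)
            par = np.cumsum(par[:, :-1], axis=1, dtype=np.int8) & 1
            use_a = (par ^ phase[:, None]) == 0
            cnt = np.zeros(m, dtype=np.int64)
            np.add.at(cnt, rows, (bps < self.center).astype(np.int64))
            use_a_center = ((cnt & 1).astype(np.int8) ^ phase) == 0
        else:
            use_a = np.broadcast_to((phase == 0)[:, None], (m, S))
            use_a_center = phase == 0
        ch_H = np.where(use_a, self.H[a_idx], self.H[b_idx])
        ch_adaptive = np.where(use_a_center, self.adaptive[a_idx], self.adaptive[b_idx])
        ch_origin = np.where(use_a_center, self.origin[a_idx], self.origin[b_idx])
        return ch_H, ch_adaptive, ch_origin

    def _trim_overshoot(self, rng, new_H, new_adaptive, new_origin, g, pf_count,
                        scale=1.0):
        """Land the crossing generation exactly on ``pf_count`` carriers.

        Excess adaptive children are replaced by children regenerated from
        fitness-weighted parents conditioned on transmitting a non-adaptive
        haplotype (the forward analogue of stopping the allele-frequency
        trajectory at PF).
        """
        excess = np.flatnonzero(new_adaptive)
        excess = rng.permutation(excess)[: int(new_adaptive.sum()) - pf_count]
        # weight = fitness x chance of a non-adaptive transmission (~ (2-g)/2)
        w_na = (1.0 + self.s_eff * g) * (2.0 - g) / 2.0
        if w_na.sum() <= 0:  # population fixed for the allele; keep overshoot
            return
        p_na = w_na / w_na.sum()
        todo = excess
        for _ in range(100):
            if todo.size == 0:
                break
            parents = rng.choice(g.size, size=todo.size, p=p_na)
            ch_H, ch_a, ch_o = self._make_children(rng, parents, scale)
            ok = ~ch_a
            fill = todo[ok]
            new_H[fill] = ch_H[ok]
            new_adaptive[fill] = False
            new_origin[fill] = -1
            todo = todo[~ok]

    def _prune(self) -> None:
        sums = self.H.sum(axis=0, dtype=np.int64)
        keep = (sums > 0) & (sums < self.nh)
        if not keep.all():
            self.H = np.ascontiguousarray(self.H[:, keep])
            self.pos = self.pos[keep]
        self._gens_since_prune = 0


def _simulate_sweep(
    model: SweepModel, rng: np.random.Generator, max_restarts: int
) -> SweepSample:
    if model.s <= 0:
        raise ValueError("sweep modes require s > 0")
    nh = 2 * model.n_prime
    G, pos = _msprime_sample(model, nh, rng, rescaled=True)
    pop = _Population(G, pos, model)
    pf_count = int(np.ceil(model.pf * nh))

    if model.mode == "sgv":
        _drift_to_f0(pop, model, rng, max_restarts)
        pop.relabel_carriers()
    else:
        pop.seed_origin(rng)

    onset = pop.snapshot()
    recurrent = model.mode == "de_novo"
    max_gens = max(2000, 10 * pop.nh)
    restarts = 0
    gens = 0
    while pop.count() < pf_count:
        pop.step(rng, selection=True, adaptive_mutation=recurrent, pf_count=pf_count)
        gens += 1
        if pop.count() == 0:
            restarts += 1
            if restarts > max_restarts:
                raise SweepLossError(
                    f"adaptive allele lost {restarts} times before reaching PF"
                )
            pop.restore(onset)
            if model.mode == "de_novo":
                # fresh first origin; the restored neutral background is
                # stationary, so no re-burn-in is needed
                pop.adaptive[:] = False
                pop.origin[:] = -1
                pop.seed_origin(rng)
        if gens > max_gens:
            raise SweepLossError(
                f"sweep did not reach PF = {model.pf} within {max_gens} generations"
            )
    final_freq = pop.count() / nh

    for _ in range(int(round(model.t_e * 2 * nh))):  # T_E * 4 N' generations
        pop.step(rng, selection=False, adaptive_mutation=False)

    return _draw_sample(pop, model, rng, final_freq)


def _drift_to_f0(
    pop: _Population, model: SweepModel, rng: np.random.Generator, max_restarts: int
) -> None:
    """Neutral first passage of a single-copy allele to frequency f0."""
    target = max(1, int(np.ceil(model.f0 * pop.nh)))
    attempts = 0
    budget = max(1000, max_restarts, 50 * target)
    start = pop.snapshot()
    pop.seed_origin(rng)
    while pop.count() < target:
        pop.step(rng, selection=False, adaptive_mutation=False)
        if pop.count() == 0:
            attempts += 1
            if attempts > budget:
                raise SweepLossError(
                    f"standing variant never reached f0 = {model.f0} "
                    f"in {attempts} attempts"
                )
            pop.restore(start)
            pop.seed_origin(rng)


def _draw_sample(
    pop: _Population,
    model: SweepModel,
    rng: np.random.Generator,
    final_freq: float,
) -> SweepSample:
    n = model.sample_size
    if n > pop.nh:
        raise ValueError(f"sample size {n} exceeds population of {pop.nh} haplotypes")
    rows = rng.choice(pop.nh, size=n, replace=False)
    sub = pop.H[rows]
    counts = sub.sum(axis=0, dtype=np.int64)
    seg = (counts > 0) & (counts < n)
    sub = sub[:, seg]
    pos = pop.pos[seg]
    labels = pop.origin[rows]
    adaptive = pop.adaptive[rows].astype(np.int8)

    adaptive_col: int | None = None
    if 0 < int(adaptive.sum()) < n:
        j = int(np.searchsorted(pos, pop.center))
        sub = np.insert(sub, j, adaptive, axis=1)
        pos = np.insert(pos, j, pop.center)
        adaptive_col = j

    bp = _fractions_to_bp(pos / model.locus_length, model.locus_length)
    matrix = HaplotypeMatrix("sim", bp, np.ascontiguousarray(sub))
    return SweepSample(
        matrix=matrix,
        mode=model.mode,
        adaptive_col=adaptive_col,
        origin_labels=np.where(pop.adaptive[rows], labels, -1),
        final_frequency=final_freq,
        locus_length=model.locus_length,
    )


# ---------------------------------------------------------------------------
# ms-format output


def write_ms(samples: list[SweepSample], path: str, command: str = "hapsweep") -> None:
    """Write samples as ms-format text consumable by ``haplodata.read_ms``.

    Positions are emitted as fractions of the locus length with enough
    precision that reading the file back reproduces the integer bp
    coordinates exactly.
    """
    if not samples:
        raise ValueError("no samples to write")
    n = samples[0].matrix.n_haplotypes
    with open(path, "w") as fh:
        fh.write(f"{command} {n} {len(samples)}\n0x0 0x0 0x0\n")
        for sample in samples:
            m = sample.matrix
            fh.write("\n//\n")
            fh.write(f"segsites: {m.n_snps}\n")
            if m.n_snps == 0:
                continue
            fracs = m.positions / sample.locus_length
            fh.write("positions: " + " ".join(f"{f:.8f}" for f in fracs) + "\n")
            for row in m.alleles:
                fh.write("".join("1" if a == 1 else "0" for a in row) + "\n")
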