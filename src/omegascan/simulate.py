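"""Rescaled forward Wright-Fisher simulator with optional conditioned sweeps.

Replicates are generated by a discrete haploid Wright-Fisher population of
M = 2 * pop_size chromosomes carrying infinite-sites mutations (fresh
uniform positions on [0, 1]) and crossover recombination.  Mutation and
recombination are parameterised by the coalescent-scaled totals
theta = 4 N mu L and rho = 4 N c L of the emulated population, so expected
sample diversity and LD decay follow the standard coalescent values
regardless of the (much smaller) forward population size.

Demography is a piecewise-constant population-size history given
backwards in time in units of 4N generations (one unit = 2M forward
generations).  Bottlenecks whose rescaled size or duration would drop
below one generation are re-expressed as an equivalent number of whole
generations at a floored size that preserves the epoch's pairwise
coalescent intensity (duration / size).

A selective sweep is simulated mssel-style: a beneficial-allele frequency
trajectory is drawn first (Wright-Fisher binomial sampling with selection
s = alpha / M under the same demography, conditioned on fixation by
rejection), and the population then evolves conditional on that
trajectory — offspring counts of the beneficial class follow the
trajectory, and a recombinant's segment containing the selected site must
come from a parent of its own class.  Sampling happens at fixation, so
the beneficial site itself is monomorphic and absent from the output.

To keep many-replicate studies affordable, one long neutral run per
parameter set is harvested at well-separated time points (burn-in
8M generations, spacing 3M generations between harvests, i.e. about
1.5 expected whole-sample coalescence times); each harvest is branched
through the demographic tail (and, for sweep replicates, the conditioned
sweep phase) before sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import Alphabet, SnpMatrix, write_ms  # re-exported: ms output format

__all__ = [
    "Epoch",
    "Sweep",
    "SimParams",
    "Trajectory",
    "DEMOGRAPHIES",
    "sample_trajectory",
    "simulate_neutral",
    "simulate_sweep",
    "simulate_paired",
    "write_ms",
]

#: Smallest chromosome count used to realise a bottleneck.  Severe
#: bottlenecks are stretched over several generations at this floor so
#: that multi-lineage coalescence stays gradual instead of collapsing
#: the whole sample in a single generation.
MIN_BOTTLENECK_SIZE = 16

BURN_IN_FACTOR = 8  # burn-in = 8 M generations (>= 10 N of the scaled model)
HARVEST_SPACING_FACTOR = 3  # generations between harvests, in units of M


@dataclass(frozen=True)
class Epoch:
    """One population-size epoch, backwards in time.

    ``start``/``end`` are in units of 4N generations before sampling
    (start is the more recent boundary); ``relative_size`` multiplies the
    present-day size.
    """

    start: float
    end: float
    relative_size: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("epoch needs 0 <= start < end (backwards)")
        if self.relative_size <= 0:
            raise ValueError("relative_size must be positive")


#: The bottleneck scenarios used throughout the simulation study
#: (begin/end backwards in units of 4N generations, relative size during).
DEMOGRAPHIES: dict[str, tuple[Epoch, ...]] = {
    "constant": (),
    "bottleneck1": (Epoch(0.100, 0.1004, 0.5),),
    "bottleneck2": (Epoch(0.015, 0.0160, 0.5),),
    "bottleneck3": (Epoch(0.015, 0.0170, 0.01),),
    "bottleneck4": (Epoch(0.015, 0.0160, 0.005),),
    "bottleneck5": (Epoch(0.015, 0.0170, 0.1),),
    "bottleneck6": (Epoch(0.010, 0.0104, 0.5),),
    "bottleneck7": (Epoch(0.010, 0.0104, 0.1),),
}


@dataclass(frozen=True)
class Sweep:
    """Selective sweep parameters.

    ``alpha`` = 2Ns of the *scaled* population (per-generation advantage
    s = alpha / M, which caps usable alpha below M); ``fixation_time`` is
    backwards from sampling in units of 4N generations (0: sample at
    fixation, a completed sweep).
    """

    position_fraction: float = 0.5
    alpha: float = 100.0
    fixation_time: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.position_fraction < 1):
            raise ValueError("sweep position must lie inside (0, 1)")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one batch of replicates.

    Defaults emulate the sensitivity-study setup: n = 50 haplotypes from
    a 1 Mb region with on the order of 3,000 segregating sites
    (theta_total = 700 gives E[S] = 700 * a_49 ~ 3,100) and enough
    recombination (rho_total = 400) that a strong sweep's LD footprint
    spans roughly a tenth of the region.
    """

    n_samples: int = 50
    pop_size: int = 80  # N: diploid individuals of the scaled population
    region_length: float = 1_000_000.0
    theta_total: float = 700.0
    rho_total: float = 400.0
    demography: str | tuple[Epoch, ...] = "constant"
    sweep: Sweep | None = None
    seed: int | None = None

    @property
    def chromosomes(self) -> int:
        return 2 * self.pop_size

    @property
    def epochs(self) -> tuple[Epoch, ...]:
        if isinstance(self.demography, str):
            try:
                return DEMOGRAPHIES[self.demography]
            except KeyError:
                raise ValueError(f"unknown demography {self.demography!r}") from None
        return tuple(self.demography)

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_samples > self.chromosomes:
            raise ValueError("need 2 <= n_samples <= 2 * pop_size")
        if self.theta_total < 0 or self.rho_total < 0:
            raise ValueError("rates must be non-negative")
        if self.sweep is not None and self.sweep.alpha >= self.chromosomes:
            raise ValueError(
                "alpha must be below 2 * pop_size for the rescaled "
                "per-generation selection coefficient to stay below 1"
            )
        _ = self.epochs  # validate name


@dataclass
class Trajectory:
    """Beneficial-allele frequency per forward generation, 1/M up to 1."""

    frequencies: np.ndarray
    pop_sizes: np.ndarray  # forward per-generation chromosome counts

    @property
    def n_generations(self) -> int:
        return self.frequencies.size - 1

    @property
    def counts(self) -> np.ndarray:
        return np.rint(self.frequencies * self.pop_sizes).astype(np.int64)


def size_schedule(params: SimParams) -> np.ndarray:
    """Per-generation chromosome counts backwards from the sampling time.

    Covers time up to the oldest epoch boundary; the population is at the
    base size M before index 0 ... after the returned horizon.  Epochs
    shorter than a generation (or bottlenecks below the size floor) are
    emitted as an intensity-preserving run of whole generations.
    """
    M = params.chromosomes
    unit = 2.0 * M  # generations per unit of 4N
    boundaries = sorted(
        {0.0}
        | {e.start * unit for e in params.epochs}
        | {e.end * unit for e in params.epochs}
    )
    sizes: list[int] = []
    for g0, g1 in zip(boundaries, boundaries[1:]):
        mid = 0.5 * (g0 + g1)
        rel = 1.0
        for e in params.epochs:
            if e.start * unit <= mid < e.end * unit:
                rel = e.relative_size
        dur = g1 - g0
        m_seg = M * rel
        intensity = dur / m_seg
        k = max(1, round(max(dur, intensity * MIN_BOTTLENECK_SIZE)))
        # k generations at size m replace `dur` generations of the segment
        # plus (k - dur) generations of base-size background
        m = max(2, round(k / (intensity + max(k - dur, 0.0) / M)))
        sizes.extend([m] * k)
    return np.array(sizes, dtype=np.int64)


class _Population:
    """Dense boolean genotype table with infinite-sites bookkeeping."""

    def __init__(self, params: SimParams, rng: np.random.Generator) -> None:
        M = params.chromosomes
        self.params = params
        self.rng = rng
        self.mu = params.theta_total / (2.0 * M)  # per chromosome per generation
        self.r = params.rho_total / (2.0 * M)
        self.capacity = 4096
        self.genomes = np.zeros((M, self.capacity), dtype=bool)
        self.positions = np.zeros(self.capacity)
        self.n_active = 0

    @property
    def size(self) -> int:
        return self.genomes.shape[0]

    def copy(self, rng: np.random.Generator) -> "_Population":
        clone = _Population.__new__(_Population)
        clone.params = self.params
        clone.rng = rng
        clone.mu, clone.r = self.mu, self.r
        clone.capacity = self.capacity
        clone.genomes = self.genomes.copy()
        clone.positions = self.positions.copy()
        clone.n_active = self.n_active
        return clone

    # -- internals ----------------------------------------------------

    def _compact(self, incoming: int) -> None:
        s = self.n_active
        counts = self.genomes[:, :s].sum(axis=0)
        keep = (counts > 0) & (counts < self.size)
        kept = int(keep.sum())
        while kept + incoming > self.capacity or kept > 0.6 * self.capacity:
            self.capacity *= 2
        new_g = np.zeros((self.size, self.capacity), dtype=bool)
        new_p = np.zeros(self.capacity)
        new_g[:, :kept] = self.genomes[:, :s][:, keep]
        new_p[:kept] = self.positions[:s][keep]
        self.genomes, self.positions, self.n_active = new_g, new_p, kept

    def _recombine(
        self,
        new: np.ndarray,
        old: np.ndarray,
        parents: np.ndarray,
        sweep_site: float | None,
    ) -> None:
        """Apply crossovers in place; ``new`` rows currently copy ``parents``.

        Each offspring draws a Poisson(r) number of crossover points and
        alternates segments between its main parent and one partner drawn
        from the whole previous generation.  When ``sweep_site`` is set
        the segment containing it is pinned to the main parent, which the
        conditioned sweep step has drawn from the offspring's own class.
        """
        m_next = new.shape[0]
        s = self.n_active
        if self.r <= 0 or s == 0:
            return
        k = self.rng.poisson(self.r, m_next)
        rec = np.flatnonzero(k)
        if rec.size == 0:
            return
        partners = self.rng.integers(0, old.shape[0], rec.size)
        pos = self.positions[:s]
        for kv in np.unique(k[rec]):
            sel = k[rec] == kv
            rows = rec[sel]
            pts = self.rng.random((rows.size, kv))
            # crossover-count parity decides which parent supplies each site
            use_partner = np.zeros((rows.size, s), dtype=bool)
            for t in range(kv):
                use_partner ^= pts[:, t, None] < pos[None, :]
            if sweep_site is None:
                flip = self.rng.integers(0, 2, rows.size, dtype=bool)[:, None]
            else:
                # pin the segment containing the selected site to the main parent
                flip = (((pts < sweep_site).sum(axis=1) & 1) == 1)[:, None]
            use_partner ^= flip
            donor = old[partners[sel], :s]
            new[rows, :s] = np.where(use_partner, donor, new[rows, :s])

    def _mutate(self, m_next: int) -> None:
        n_mut = self.rng.poisson(m_next * self.mu)
        if n_mut == 0:
            return
        if self.n_active + n_mut > self.capacity:
            self._compact(n_mut)
        sites = self.rng.random(n_mut)
        sites = np.unique(sites)  # infinite sites: drop within-batch collisions
        n_mut = sites.size
        carriers = self.rng.integers(0, m_next, n_mut)
        cols = np.arange(self.n_active, self.n_active + n_mut)
        self.genomes[:, cols] = False
        self.genomes[carriers, cols] = True
        self.positions[cols] = sites
        self.n_active += n_mut

    # -- generation steps ---------------------------------------------

    def _offspring(self, old: np.ndarray, parents: np.ndarray) -> np.ndarray:
        """Copy the active columns of the chosen parents into a fresh table."""
        new = np.empty((parents.size, self.capacity), dtype=bool)
        new[:, : self.n_active] = old[parents, : self.n_active]
        return new

    def step(self, m_next: int) -> None:
        """One neutral Wright-Fisher generation to a population of m_next."""
        old = self.genomes
        parents = self.rng.integers(0, self.size, m_next)
        new = self._offspring(old, parents)
        self._recombine(new, old, parents, None)
        self.genomes = new
        self._mutate(m_next)

    def step_conditioned(
        self, m_next: int, ben_cur: int, ben_next: int, sweep_site: float
    ) -> None:
        """One generation conditioned on the sweep trajectory.

        Rows [0, ben) hold the beneficial class; beneficial offspring
        draw their main parent from the beneficial class and the others
        from the neutral class, so class counts follow the trajectory.
        """
        old = self.genomes
        parents = np.empty(m_next, dtype=np.int64)
        parents[:ben_next] = self.rng.integers(0, max(ben_cur, 1), ben_next)
        if m_next - ben_next:
            lo, hi = ben_cur, self.size
            if hi <= lo:  # trajectory already fixed; neutral class empty
                lo, hi = 0, self.size
            parents[ben_next:] = self.rng.integers(lo, hi, m_next - ben_next)
        new = self._offspring(old, parents)
        self._recombine(new, old, parents, sweep_site)
        self.genomes = new
        self._mutate(m_next)

    def run(self, generations: int) -> None:
        for _ in range(generations):
            self.step(self.size)

    def run_schedule(self, sizes_forward: np.ndarray) -> None:
        for m in sizes_forward:
            self.step(int(m))

    # -- output -------------------------------------------------------

    def sample(self, n: int) -> SnpMatrix:
        """Draw n haplotypes and keep their polymorphic sites."""
        rows = self.rng.choice(self.size, n, replace=False)
        s = self.n_active
        codes = self.genomes[rows, :s]
        counts = codes.sum(axis=0)
        poly = (counts > 0) & (counts < n)
        codes = codes[:, poly]
        pos = self.positions[:s][poly]
        order = np.argsort(pos, kind="stable")
        pos, codes = pos[order], codes[:, order]
        # float positions are almost surely distinct; enforce it regardless
        for i in range(1, pos.size):
            if pos[i] <= pos[i - 1]:
                pos[i] = np.nextafter(pos[i - 1], np.inf)
        return SnpMatrix.from_codes(
            codes.astype(np.int8),
            pos * self.params.region_length,
            Alphabet.BINARY,
            require_polymorphic=False,
        )


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

_TRAJECTORY_RETRY_CAP = 100_000


def _attempt_trajectory(
    s: float, sizes_back: np.ndarray, base: int, t_guess: int, rng: np.random.Generator
) -> np.ndarray | None:
    """One conditioned draw assuming the sweep lasts ``t_guess`` generations."""

    def size_at(back_gen: int) -> int:
        return int(sizes_back[back_gen]) if 0 <= back_gen < sizes_back.size else base

    # forward step t produces the generation at backwards index t_guess - t,
    # so fixation (t = t_guess) lands on backwards index 0
    m = size_at(t_guess)
    k = 1
    freqs = [k / m]
    for t in range(1, 50 * t_guess + 1000):
        m_next = size_at(t_guess - t)
        x = k / m
        p = (1.0 + s) * x / (1.0 + s * x)
        k = int(rng.binomial(m_next, p))
        m = m_next
        if k == 0:
            return None
        freqs.append(k / m)
        if k == m:
            return np.array(freqs)
    return None


def sample_trajectory(
    params: SimParams, seed: int | np.random.Generator | None = None
) -> Trajectory:
    """Draw a beneficial-allele trajectory conditioned on fixation.

    Forward-in-time Wright-Fisher binomial sampling with selection
    s = alpha / M under the demographic size schedule, rejected and
    redrawn until the allele fixes.  The schedule is aligned so that
    fixation lands at ``sweep.fixation_time`` before sampling; because
    the (random) sweep duration determines which epoch sizes it
    overlaps, the alignment is iterated to a fixed point.
    """
    if params.sweep is None:
        raise ValueError("params.sweep must be set")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(params.seed if seed is None else seed)
    )
    M = params.chromosomes
    s = params.sweep.alpha / M
    offset = int(round(params.sweep.fixation_time * 2 * M))
    sched = size_schedule(params)[offset:]
    t_guess = max(4, int(round(2.0 * np.log(M) / s)))
    freqs: np.ndarray | None = None
    for _ in range(_TRAJECTORY_RETRY_CAP):
        freqs = _attempt_trajectory(s, sched, M, t_guess, rng)
        if freqs is None:
            continue
        if freqs.size - 1 == t_guess:
            break
        t_guess = freqs.size - 1  # realign epochs to the drawn duration
    if freqs is None:
        raise RuntimeError("trajectory conditioning exceeded the retry cap")
    t = freqs.size - 1
    sizes_fw = np.array(
        [int(sched[t - i]) if 0 <= t - i < sched.size else M for i in range(t + 1)],
        dtype=np.int64,
    )
    return Trajectory(freqs, sizes_fw)


# ---------------------------------------------------------------------------
# replicate generation
# ---------------------------------------------------------------------------


def _equilibrium_run(
    params: SimParams, reps: int, seed, branch_fn
) -> list:
    """Burn in one long neutral run and branch a replicate per harvest."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    M = params.chromosomes
    pop = _Population(params, rng)
    pop.run(BURN_IN_FACTOR * M)
    out = []
    for _ in range(reps):
        pop.run(HARVEST_SPACING_FACTOR * M)
        out.append(branch_fn(pop, rng))
    return out


def _neutral_branch(
    params: SimParams,
    sched_back: np.ndarray,
    pop: _Population,
    rng: np.random.Generator,
) -> SnpMatrix:
    child = pop.copy(rng)
    child.run_schedule(sched_back[::-1])
    return child.sample(params.n_samples)


def _sweep_branch(
    params: SimParams,
    sched_back: np.ndarray,
    pop: _Population,
    rng: np.random.Generator,
) -> SnpMatrix:
    sweep = params.sweep
    offset = int(round(sweep.fixation_time * 2 * params.chromosomes))
    traj = sample_trajectory(params, rng)
    t = traj.n_generations
    child = pop.copy(rng)
    # neutral demographic history older than the sweep start
    deep = sched_back[offset + t :]
    if deep.size:
        child.run_schedule(deep[::-1])
    sizes = traj.pop_sizes
    counts = np.clip(traj.counts, 1, sizes)
    counts[0] = 1
    counts[t] = sizes[t]
    for i in range(1, t + 1):
        child.step_conditioned(
            int(sizes[i]), int(counts[i - 1]), int(counts[i]), sweep.position_fraction
        )
    # post-fixation neutral generations (incomplete-sweep sampling delay)
    post = sched_back[:offset]
    if post.size:
        child.run_schedule(post[::-1])
    return child.sample(params.n_samples)


def simulate_neutral(
    params: SimParams, reps: int, seed: int | None = None
) -> list[SnpMatrix]:
    """Neutral replicates under the configured demography."""
    sched_back = size_schedule(params)
    return _equilibrium_run(
        params,
        reps,
        seed,
        lambda pop, rng: _neutral_branch(params, sched_back, pop, rng.spawn(1)[0]),
    )


def simulate_sweep(
    params: SimParams, reps: int, seed: int | None = None
) -> list[SnpMatrix]:
    """Replicates with a sweep fixing at the configured site and time."""
    if params.sweep is None:
        raise ValueError("params.sweep must be set")
    sched_back = size_schedule(params)
    return _equilibrium_run(
        params,
        reps,
        seed,
        lambda pop, rng: _sweep_branch(params, sched_back, pop, rng.spawn(1)[0]),
    )


def simulate_paired(
    params: SimParams, reps: int, seed: int | None = None
) -> tuple[list[SnpMatrix], list[SnpMatrix]]:
    """Matched neutral and sweep replicates branched from shared harvests.

    Each harvest of the long equilibrium run is branched twice — once
    through the neutral demographic tail and once through the conditioned
    sweep phase — so a calibration/selection pair costs one harvest.
    Returns (neutral, sweep) lists of equal length.
    """
    if params.sweep is None:
        raise ValueError("params.sweep must be set")
    sched_back = size_schedule(params)

    def branch(pop: _Population, rng: np.random.Generator):
        r_neu, r_sw = rng.spawn(2)
        return (
            _neutral_branch(params, sched_back, pop, r_neu),
            _sweep_branch(params, sched_back, pop, r_sw),
        )

    pairs = _equilibrium_run(params, reps, seed, branch)
    return [p[0] for p in pairs], [p[1] for p in pairs]
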