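"""Exact stochastic simulation of the two-locus ancestral process with
time-stratified sampling.

Two engines live here, both exact continuous-time Markov chain (Gillespie)
simulations — exponential waiting times and categorical event choices, no
time discretisation:

* a vectorised two-haplotype engine (:func:`simulate_pairs` and friends) used
  as the Monte-Carlo oracle for the closed forms in :mod:`stratld.theory`,
  in coalescent units or, with a piecewise-constant demography, in
  generations;
* a general n-haplotype engine (:func:`simulate_panel`) that tracks ancestral
  material per lineage at both loci, builds the marginal genealogy at each
  locus, and drops infinite-sites mutations to produce binary haplotype
  panels with per-haplotype sampling times.

Event rates follow the coalescent-unit convention matching ``rho = 4*Ne*r``:
each coupled (ab) lineage recombines at rate ``rho/2`` and every unordered
pair of lineages coalesces at rate 1 (or ``1/(2*Ne(t))`` per generation in
demography mode, where the recombination hazard is the per-generation ``r``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .haplotypes import HaplotypeMatrix
from .hapstats import pearson_se
from .theory import TwoLocusParams

__all__ = [
    "Demography",
    "TwoLocusGenealogy",
    "TwoLocusReplicates",
    "HaplotypeSampleConfig",
    "TwoLocusPanel",
    "simulate_pair",
    "simulate_pairs",
    "simulate_pair_demography",
    "simulate_pairs_demography",
    "pairwise_coal_times",
    "effective_ne_pairwise",
    "mc_corr_branch_length",
    "mc_corr_pairwise_diff",
    "simulate_panel",
]


@dataclass(frozen=True)
class Demography:
    """Piecewise-constant population-size history.

    ``epochs`` is an ordered list of ``(start_time_generations, Ne)`` pairs;
    the first start time must be 0 and start times strictly increase going
    into the past.  ``Ne`` is the diploid effective size during the epoch.
    """

    epochs: tuple

    def __init__(self, epochs):
        epochs = tuple((float(s), float(n)) for s, n in epochs)
        if not epochs:
            raise ValueError("demography needs at least one epoch")
        starts = [s for s, _ in epochs]
        if starts[0] != 0.0:
            raise ValueError("first epoch must start at time 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("epoch start times must be strictly increasing")
        if any(not np.isfinite(n) or n <= 0 for _, n in epochs):
            raise ValueError("all Ne must be positive and finite")
        object.__setattr__(self, "epochs", epochs)

    @property
    def starts(self) -> np.ndarray:
        return np.array([s for s, _ in self.epochs])

    @property
    def sizes(self) -> np.ndarray:
        return np.array([n for _, n in self.epochs])

    @classmethod
    def constant(cls, ne: float) -> "Demography":
        return cls([(0.0, ne)])


@dataclass(frozen=True)
class TwoLocusGenealogy:
    """One replicate of the two-haplotype, two-locus ancestral process.

    ``T_A``/``T_B`` are coalescence times at each locus measured from the
    ancient sampling time; total branch lengths are ``L = t_a + 2*T``.
    Units (coalescent or generations) follow the simulating call.
    """

    T_A: float
    T_B: float
    L_A: float
    L_B: float
    uncoupled_at_ta: bool
    t_a: float


@dataclass(frozen=True)
class TwoLocusReplicates:
    """Vectorised collection of pair replicates (see :class:`TwoLocusGenealogy`)."""

    T_A: np.ndarray
    T_B: np.ndarray
    L_A: np.ndarray
    L_B: np.ndarray
    uncoupled_at_ta: np.ndarray
    t_a: float

    def __len__(self) -> int:
        return self.T_A.size

    def __getitem__(self, i: int) -> TwoLocusGenealogy:
        return TwoLocusGenealogy(
            float(self.T_A[i]), float(self.T_B[i]), float(self.L_A[i]),
            float(self.L_B[i]), bool(self.uncoupled_at_ta[i]), self.t_a,
        )


@dataclass(frozen=True)
class HaplotypeSampleConfig:
    """Sampling design for panel simulation: haplotype counts and ages.

    ``t_a`` is the age of the ancient haplotypes in coalescent units; pass
    ``times`` for fully general per-haplotype ages instead.
    """

    n_modern: int = 0
    n_ancient: int = 0
    t_a: float = 0.0
    times: np.ndarray | None = None

    def __post_init__(self):
        if self.times is not None:
            times = np.asarray(self.times, dtype=float)
            if times.size < 2:
                raise ValueError("need at least 2 haplotypes")
            if np.any(times < 0):
                raise ValueError("sampling times must be >= 0")
            object.__setattr__(self, "times", times)
        else:
            if self.n_modern < 0 or self.n_ancient < 0:
                raise ValueError("haplotype counts must be >= 0")
            if self.n_modern + self.n_ancient < 2:
                raise ValueError("need at least 2 haplotypes")
            if self.t_a < 0:
                raise ValueError("t_a must be >= 0")

    @property
    def sample_times(self) -> np.ndarray:
        if self.times is not None:
            return self.times
        return np.concatenate(
            [np.zeros(self.n_modern), np.full(self.n_ancient, float(self.t_a))]
        )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if not isinstance(seed, (int, np.integer, np.random.SeedSequence)):
        raise TypeError(f"rng_seed must be an int or numpy Generator, got {type(seed)}")
    return np.random.default_rng(seed)


# -- two-haplotype engine, coalescent units -----------------------------------

def _phase1_uncoupled(rho: float, t_a: float, n: int, rng) -> np.ndarray:
    """Gillespie simulation of the coupled/uncoupled two-state chain to t_a."""
    uncoupled = np.zeros(n, dtype=bool)
    if t_a <= 0 or n == 0:
        return uncoupled
    t = np.zeros(n)
    idx = np.arange(n)
    while idx.size:
        rates = np.where(uncoupled[idx], 1.0, rho / 2.0)
        dt = np.full(idx.size, np.inf)
        pos = rates > 0
        dt[pos] = rng.exponential(1.0, int(pos.sum())) / rates[pos]
        t[idx] += dt
        jumped = t[idx] < t_a
        flip = idx[jumped]
        uncoupled[flip] = ~uncoupled[flip]
        idx = flip
    return uncoupled


# phase-2 lineage configurations for a modern+ancient pair
_S0, _S1, _S2, _S3, _S4, _DONE = range(6)  # (2ab) (ab,a,b) (a,a,b,b) B-open A-open done


def _phase2_times(rho: float, uncoupled0: np.ndarray, rng):
    """Gillespie over the two-sample lineage configurations from t_a onward.

    Returns post-t_a marginal coalescence times (T_A, T_B).
    """
    n = uncoupled0.size
    half = rho / 2.0
    state = np.where(uncoupled0, _S1, _S0).astype(np.int8)
    t = np.zeros(n)
    t_a_arr = np.full(n, np.nan)
    t_b_arr = np.full(n, np.nan)
    total_rate = np.array([rho + 1.0, half + 3.0, 6.0, 1.0, 1.0, np.nan])
    idx = np.arange(n)
    while idx.size:
        s = state[idx]
        tot = total_rate[s]
        t[idx] += rng.exponential(1.0, idx.size) / tot
        u = rng.random(idx.size) * tot
        tt = t[idx]
        ns = s.copy()

        m = s == _S0
        rec = m & (u < rho)
        ns[rec] = _S1
        absorb = m & ~rec  # ab+ab coalescence closes both loci at once
        t_a_arr[idx[absorb]] = tt[absorb]
        t_b_arr[idx[absorb]] = tt[absorb]
        ns[absorb] = _DONE

        m = s == _S1
        ns[m & (u < half)] = _S2
        e = m & (u >= half) & (u < half + 1.0)  # ab+a: locus A coalesces
        t_a_arr[idx[e]] = tt[e]
        ns[e] = _S3
        e = m & (u >= half + 1.0) & (u < half + 2.0)  # ab+b: locus B coalesces
        t_b_arr[idx[e]] = tt[e]
        ns[e] = _S4
        ns[m & (u >= half + 2.0)] = _S0  # a+b re-couple

        m = s == _S2
        e = m & (u < 1.0)  # a+a
        t_a_arr[idx[e]] = tt[e]
        ns[e] = _S3
        e = m & (u >= 1.0) & (u < 2.0)  # b+b
        t_b_arr[idx[e]] = tt[e]
        ns[e] = _S4
        ns[m & (u >= 2.0)] = _S1  # one of 4 a+b pairs re-couples

        m = s == _S3
        t_b_arr[idx[m]] = tt[m]
        ns[m] = _DONE
        m = s == _S4
        t_a_arr[idx[m]] = tt[m]
        ns[m] = _DONE

        state[idx] = ns
        idx = idx[ns != _DONE]
    return t_a_arr, t_b_arr


def simulate_pairs(params: TwoLocusParams, n_reps: int, rng_seed) -> TwoLocusReplicates:
    """Simulate ``n_reps`` independent modern+ancient pair genealogies.

    Times are in coalescent units; total branch length ``L = t_a + 2*T``.
    """
    rng = _as_rng(rng_seed)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rho, t_a = params.rho, params.t_a
    uncoupled = _phase1_uncoupled(rho, t_a, n_reps, rng)
    ta_post, tb_post = _phase2_times(rho, uncoupled, rng)
    return TwoLocusReplicates(
        T_A=ta_post,
        T_B=tb_post,
        L_A=t_a + 2.0 * ta_post,
        L_B=t_a + 2.0 * tb_post,
        uncoupled_at_ta=uncoupled,
        t_a=t_a,
    )


def simulate_pair(params: TwoLocusParams, rng_seed) -> TwoLocusGenealogy:
    """Simulate a single modern+ancient pair genealogy (coalescent units)."""
    return simulate_pairs(params, 1, rng_seed)[0]


# -- two-haplotype engine, generations + demography ---------------------------

def _epoch_of(times: np.ndarray, starts: np.ndarray) -> np.ndarray:
    return np.maximum(np.searchsorted(starts, times, side="right") - 1, 0)


def _phase1_uncoupled_demog(r, t_a, dem: Demography, n, rng):
    starts = np.append(dem.starts, np.inf)
    crates = 1.0 / (2.0 * dem.sizes)
    uncoupled = np.zeros(n, dtype=bool)
    if t_a <= 0:
        return uncoupled
    t = np.zeros(n)
    ep = np.zeros(n, dtype=np.int64)
    idx = np.arange(n)
    while idx.size:
        rates = np.where(uncoupled[idx], crates[ep[idx]], r)
        cap = np.minimum(t_a, starts[ep[idx] + 1])
        dt = np.full(idx.size, np.inf)
        pos = rates > 0
        dt[pos] = rng.exponential(1.0, int(pos.sum())) / rates[pos]
        tn = t[idx] + dt
        jump = tn < cap
        j = idx[jump]
        uncoupled[j] = ~uncoupled[j]
        t[j] = tn[jump]
        hit_epoch = ~jump & (cap < t_a)
        h = idx[hit_epoch]
        t[h] = cap[hit_epoch]
        ep[h] += 1
        idx = np.concatenate([j, h])
    return uncoupled


_REC_MULT = np.array([2.0, 1.0, 0.0, 0.0, 0.0, np.nan])
_COAL_MULT = np.array([1.0, 3.0, 6.0, 1.0, 1.0, np.nan])


def _phase2_times_demog(r, t_a, dem: Demography, uncoupled0, rng):
    starts = np.append(dem.starts, np.inf)
    crates = 1.0 / (2.0 * dem.sizes)
    n = uncoupled0.size
    state = np.where(uncoupled0, _S1, _S0).astype(np.int8)
    t = np.full(n, float(t_a))
    ep = _epoch_of(t, dem.starts)
    t_a_arr = np.full(n, np.nan)
    t_b_arr = np.full(n, np.nan)
    idx = np.arange(n)
    while idx.size:
        s = state[idx]
        c = crates[ep[idx]]
        rr = r * _REC_MULT[s]
        tot = rr + c * _COAL_MULT[s]
        tn = t[idx] + rng.exponential(1.0, idx.size) / tot
        eb = starts[ep[idx] + 1]
        cross = tn >= eb
        x = idx[cross]
        t[x] = eb[cross]
        ep[x] += 1  # memoryless: redraw waiting time in the next epoch

        act = ~cross
        ai = idx[act]
        t[ai] = tn[act]
        u = rng.random(ai.size) * tot[act]
        sa = s[act]
        ca = c[act]
        ra = rr[act]
        tt = t[ai]
        ns = sa.copy()

        m = sa == _S0
        rec = m & (u < ra)
        ns[rec] = _S1
        absorb = m & ~rec
        t_a_arr[ai[absorb]] = tt[absorb]
        t_b_arr[ai[absorb]] = tt[absorb]
        ns[absorb] = _DONE

        m = sa == _S1
        ns[m & (u < ra)] = _S2
        e = m & (u >= ra) & (u < ra + ca)
        t_a_arr[ai[e]] = tt[e]
        ns[e] = _S3
        e = m & (u >= ra + ca) & (u < ra + 2 * ca)
        t_b_arr[ai[e]] = tt[e]
        ns[e] = _S4
        ns[m & (u >= ra + 2 * ca)] = _S0

        m = sa == _S2
        e = m & (u < ca)
        t_a_arr[ai[e]] = tt[e]
        ns[e] = _S3
        e = m & (u >= ca) & (u < 2 * ca)
        t_b_arr[ai[e]] = tt[e]
        ns[e] = _S4
        ns[m & (u >= 2 * ca)] = _S1

        m = sa == _S3
        t_b_arr[ai[m]] = tt[m]
        ns[m] = _DONE
        m = sa == _S4
        t_a_arr[ai[m]] = tt[m]
        ns[m] = _DONE

        state[ai] = ns
        idx = np.concatenate([ai[ns != _DONE], x])
    return t_a_arr - t_a, t_b_arr - t_a


def simulate_pairs_demography(
    r_per_gen: float, t_a_gens: float, demography: Demography, n_reps: int, rng_seed
) -> TwoLocusReplicates:
    """Pair genealogies in generation units under a piecewise-constant demography.

    Recombination hazard is ``r_per_gen`` per coupled lineage per generation;
    each lineage pair coalesces at rate ``1/(2*Ne(t))`` per generation, with
    exact epoch-wise simulation (no Euler stepping).  With a single epoch this
    reduces to :func:`simulate_pairs` under the change of units
    ``rho = 4*Ne*r``, ``t_coal = t_gens/(2*Ne)``.
    """
    if r_per_gen < 0 or t_a_gens < 0:
        raise ValueError("r_per_gen and t_a_gens must be >= 0")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = _as_rng(rng_seed)
    uncoupled = _phase1_uncoupled_demog(r_per_gen, t_a_gens, demography, n_reps, rng)
    ta_post, tb_post = _phase2_times_demog(r_per_gen, t_a_gens, demography, uncoupled, rng)
    return TwoLocusReplicates(
        T_A=ta_post,
        T_B=tb_post,
        L_A=t_a_gens + 2.0 * ta_post,
        L_B=t_a_gens + 2.0 * tb_post,
        uncoupled_at_ta=uncoupled,
        t_a=t_a_gens,
    )


def simulate_pair_demography(
    r_per_gen: float, t_a_gens: float, demography: Demography, rng_seed
) -> TwoLocusGenealogy:
    """Single pair replicate in generation units (see :func:`simulate_pairs_demography`)."""
    return simulate_pairs_demography(r_per_gen, t_a_gens, demography, 1, rng_seed)[0]


def pairwise_coal_times(demography: Demography, n_reps: int, rng_seed) -> np.ndarray:
    """Marginal pairwise coalescence times T2 (generations) under the demography."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = _as_rng(rng_seed)
    starts = np.append(demography.starts, np.inf)
    scales = 2.0 * demography.sizes  # mean waiting time within each epoch
    t = np.zeros(n_reps)
    ep = np.zeros(n_reps, dtype=np.int64)
    idx = np.arange(n_reps)
    out = np.empty(n_reps)
    while idx.size:
        tn = t[idx] + rng.exponential(scales[ep[idx]], idx.size)
        eb = starts[ep[idx] + 1]
        cross = tn >= eb
        x = idx[cross]
        t[x] = eb[cross]
        ep[x] += 1
        done = idx[~cross]
        out[done] = tn[~cross]
        idx = x
    return out


def effective_ne_pairwise(demography: Demography, n_reps: int, rng_seed) -> float:
    """Pairwise-coalescent effective size: mean simulated T2 divided by 2."""
    t2 = pairwise_coal_times(demography, n_reps, rng_seed)
    return float(np.mean(t2) / 2.0)


# -- Monte-Carlo estimators over pair replicates ------------------------------

def mc_corr_branch_length(params: TwoLocusParams, n_reps: int, rng_seed):
    """Monte-Carlo ``Corr(L_A, L_B)`` with its asymptotic Pearson SE.

    At ``rho = 0`` the two loci share one genealogy and the correlation is
    exactly 1 with no sampling error, so ``(1.0, 0.0)`` is returned directly.
    """
    if n_reps < 10:
        raise ValueError("n_reps must be >= 10")
    if params.rho == 0:
        return 1.0, 0.0
    reps = simulate_pairs(params, n_reps, rng_seed)
    r = float(stats.pearsonr(reps.L_A, reps.L_B).statistic)
    return r, pearson_se(r, n_reps)


def mc_corr_pairwise_diff(params: TwoLocusParams, n_reps: int, rng_seed):
    """Monte-Carlo ``Corr(pi_A, pi_B)`` with its asymptotic Pearson SE.

    Pairwise differences for a two-haplotype sample at a non-recombining
    infinite-sites locus are Poisson with mean ``theta/2 * L``; they are drawn
    on top of the simulated branch lengths.
    """
    if params.theta is None:
        raise ValueError("mc_corr_pairwise_diff requires theta")
    if n_reps < 10:
        raise ValueError("n_reps must be >= 10")
    rng = _as_rng(rng_seed)
    reps = simulate_pairs(params, n_reps, rng)
    pi_a = rng.poisson(params.theta / 2.0 * reps.L_A)
    pi_b = rng.poisson(params.theta / 2.0 * reps.L_B)
    if pi_a.std() == 0 or pi_b.std() == 0:
        raise ValueError("degenerate pairwise-difference sample (zero variance); increase theta or n_reps")
    r = float(stats.pearsonr(pi_a, pi_b).statistic)
    return r, pearson_se(r, n_reps)


# -- n-haplotype panel engine -------------------------------------------------

class _Lineage:
    __slots__ = ("a", "b", "birth", "apos", "abpos")

    def __init__(self, a: int, b: int, birth: float):
        self.a = a          # bitmask of descendant haplotypes at locus A
        self.b = b          # bitmask at locus B
        self.birth = birth
        self.apos = -1      # index in the active list
        self.abpos = -1     # index in the ab-type list, -1 if not coupled


@dataclass(frozen=True)
class TwoLocusPanel:
    """Output of :func:`simulate_panel`: haplotypes plus genealogy summaries."""

    haps: HaplotypeMatrix
    sample_times_coal: np.ndarray
    t_mrca_a: float
    t_mrca_b: float
    L_a: float
    L_b: float
    params: TwoLocusParams = field(repr=False)


def simulate_panel(
    params: TwoLocusParams,
    config: HaplotypeSampleConfig,
    rng_seed,
    locus_bp: int = 10_000,
    map_separation: float | None = None,
    ne_ref: float = 10_000.0,
) -> TwoLocusPanel:
    """Simulate a two-locus haplotype panel with serial sampling.

    Runs the n-sample two-locus ancestral process (coalescent units),
    recording per-lineage ancestral material at both loci, then drops
    infinite-sites mutations on each locus's marginal genealogy as a Poisson
    process with rate ``theta/2`` per unit branch length.  Returns a binary
    haplotype matrix with one column block per locus (contigs ``locusA`` /
    ``locusB``), basepair positions uniform within each locus, and genetic map
    positions 0 and ``map_separation`` Morgans (default ``rho/(4*ne_ref)``).

    ``HaplotypeMatrix.sample_times`` are reported in generations using
    ``ne_ref`` (ages are ``t_coal * 2 * ne_ref``).
    """
    if params.theta is None or params.theta < 0:
        raise ValueError("simulate_panel requires theta >= 0")
    rng = _as_rng(rng_seed)
    times = config.sample_times
    n = times.size
    rho = params.rho
    half = rho / 2.0
    theta = params.theta

    order = np.argsort(times, kind="stable")
    act_times = times[order]
    full_mask = (1 << n) - 1

    # batched scalar RNG draws: the event loop consumes them one at a time
    class _Buf:
        def __init__(self, rng, size=8192):
            self.rng, self.size = rng, size
            self._e = rng.exponential(1.0, size)
            self._u = rng.random(size)
            self.ie = self.iu = 0

        def exp(self):
            if self.ie == self.size:
                self._e = self.rng.exponential(1.0, self.size)
                self.ie = 0
            v = self._e[self.ie]
            self.ie += 1
            return v

        def unif(self):
            if self.iu == self.size:
                self._u = self.rng.random(self.size)
                self.iu = 0
            v = self._u[self.iu]
            self.iu += 1
            return v

    buf = _Buf(rng)
    active: list[_Lineage] = []
    ab: list[_Lineage] = []
    segs: list[tuple[float, float, int, int]] = []

    def add(lin: _Lineage):
        lin.apos = len(active)
        active.append(lin)
        if lin.a and lin.b:
            lin.abpos = len(ab)
            ab.append(lin)
        else:
            lin.abpos = -1

    def remove(lin: _Lineage):
        last = active[-1]
        active[lin.apos] = last
        last.apos = lin.apos
        active.pop()
        if lin.abpos >= 0:
            lastab = ab[-1]
            ab[lin.abpos] = lastab
            lastab.abpos = lin.abpos
            ab.pop()
            lin.abpos = -1

    def emit(lin: _Lineage, t: float):
        if t > lin.birth:
            segs.append((lin.birth, t, lin.a, lin.b))

    done_a = done_b = False
    t_mrca = {"a": np.nan, "b": np.nan}

    def close_locus(which: str, t: float):
        # after a locus reaches its MRCA, material at that locus can no
        # longer affect the other locus's genealogy and is dropped
        for lin in list(active):
            emit(lin, t)
            lin.birth = t
            if which == "a":
                lin.a = 0
            else:
                lin.b = 0
            if lin.abpos >= 0:  # no longer coupled
                lastab = ab[-1]
                ab[lin.abpos] = lastab
                lastab.abpos = lin.abpos
                ab.pop()
                lin.abpos = -1
            if lin.a == 0 and lin.b == 0:
                remove(lin)

    t = 0.0
    k = 0
    while k < n and act_times[k] <= t:
        add(_Lineage(1 << int(order[k]), 1 << int(order[k]), act_times[k]))
        k += 1

    while not (done_a and done_b):
        n_act = len(active)
        n_ab = len(ab)
        crate = n_act * (n_act - 1) / 2.0
        rrate = n_ab * half
        total = crate + rrate
        t_next = act_times[k] if k < n else np.inf
        if total <= 0.0:
            if not np.isfinite(t_next):  # pragma: no cover - unreachable for valid configs
                raise RuntimeError("ancestral process stalled")
            t = t_next
        else:
            dt = buf.exp() / total
            if t + dt >= t_next:
                t = t_next
            else:
                t += dt
                if buf.unif() * total < rrate:
                    lin = ab[int(buf.unif() * n_ab)]
                    emit(lin, t)
                    remove(lin)
                    add(_Lineage(lin.a, 0, t))
                    add(_Lineage(0, lin.b, t))
                else:
                    i = int(buf.unif() * n_act)
                    j = int(buf.unif() * (n_act - 1))
                    if j >= i:
                        j += 1
                    l1, l2 = active[i], active[j]
                    emit(l1, t)
                    emit(l2, t)
                    remove(l1)
                    remove(l2)
                    merged = _Lineage(l1.a | l2.a, l1.b | l2.b, t)
                    if not done_a and merged.a == full_mask:
                        done_a = True
                        t_mrca["a"] = t
                        merged.a = 0
                        close_locus("a", t)
                    if not done_b and merged.b == full_mask:
                        done_b = True
                        t_mrca["b"] = t
                        merged.b = 0
                        close_locus("b", t)
                    if merged.a or merged.b:
                        add(merged)
                continue
        # activation point reached: add all haplotypes sampled at this time
        while k < n and act_times[k] <= t:
            add(_Lineage(1 << int(order[k]), 1 << int(order[k]), act_times[k]))
            k += 1

    # mutation dropping on each locus's marginal genealogy
    seg_arr = np.array([(s[0], s[1]) for s in segs])
    durations = seg_arr[:, 1] - seg_arr[:, 0]
    masks_a = np.array([s[2] for s in segs], dtype=object)
    masks_b = np.array([s[3] for s in segs], dtype=object)

    def mutate(masks, sel):
        cols = []
        counts = rng.poisson(theta / 2.0 * durations[sel])
        for mask, cnt in zip(masks[sel], counts):
            if cnt == 0:
                continue
            byts = int(mask).to_bytes((n + 7) // 8, "little")
            bits = np.unpackbits(np.frombuffer(byts, dtype=np.uint8), bitorder="little")[:n]
            for _ in range(int(cnt)):
                cols.append(bits.astype(np.int8))
        return cols

    sel_a = np.array([bool(m) for m in masks_a])
    sel_b = np.array([bool(m) for m in masks_b])
    cols_a = mutate(masks_a, sel_a)
    cols_b = mutate(masks_b, sel_b)
    L_a = float(durations[sel_a].sum())
    L_b = float(durations[sel_b].sum())

    sep = map_separation if map_separation is not None else rho / (4.0 * ne_ref)
    s_a, s_b = len(cols_a), len(cols_b)
    geno = np.zeros((n, s_a + s_b), dtype=np.int8)
    for j, c in enumerate(cols_a):
        geno[:, j] = c
    for j, c in enumerate(cols_b):
        geno[:, s_a + j] = c
    pos_a = np.sort(rng.choice(locus_bp, size=s_a, replace=False)) + 1 if s_a else np.array([], int)
    pos_b = np.sort(rng.choice(locus_bp, size=s_b, replace=False)) + 1 if s_b else np.array([], int)
    haps = HaplotypeMatrix(
        genotypes=geno,
        positions_bp=np.concatenate([pos_a, pos_b]).astype(np.int64),
        map_pos=np.concatenate([np.zeros(s_a), np.full(s_b, sep)]),
        sample_times=times * 2.0 * ne_ref,
        chrom=np.array(["locusA"] * s_a + ["locusB"] * s_b, dtype=object),
    )
    return TwoLocusPanel(
        haps=haps,
        sample_times_coal=times,
        t_mrca_a=float(t_mrca["a"]),
        t_mrca_b=float(t_mrca["b"]),
        L_a=L_a,
        L_b=L_b,
        params=params,
    )
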