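"""Two-population split-model theory for geographic distribution codes.

The model: two Wright-Fisher populations of N diploid individuals each,
diverged from a common population of N individuals a scaled time ``t_over_2n``
ago, with an optional recent reciprocal admixture pulse in which each sampled
lineage in one population derives from the other with probability ``alpha``.
Codes are assigned to the mutant (derived) allele from its sample frequencies
in ``n_sample`` diploids per population, using the same strict rare/common
rule as the data-side encoder, and proportions are reported among sites
segregating in the pooled sample.

Time convention: ``t_over_2n`` is the drift-scaled divergence time in the
4N-generation units used by ms-style coalescent tools, so the shallow
scenario 0.05 corresponds to T = 4,000 generations at N = 2x10^4. The
single-population drift heuristics (:func:`typical_frequency_change`,
trajectories, extinction) work directly in generations with 2N genome
copies. See docs/methods.md for the calibration discussion.

Two independent computation paths are provided for the expected code
distribution: the coalescent expectation of the joint sample site-frequency
spectrum (expected branch lengths, via msprime replicate genealogies) and a
deterministic Wright-Fisher transition-matrix (diffusion-grid) calculation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.stats import binom as binom_dist

from .geocode import _as_fraction

TWO_POP_CODES = ("Ru", "uR", "Cu", "uC", "RR", "RC", "CR", "CC")


@dataclass(frozen=True)
class SplitModelParams:
    """Parameters of the two-population split model.

    N is the diploid effective size per population; ``t_over_2n`` the scaled
    divergence time (0.05 shallow, 0.5 deep; 4N-generation drift units);
    ``alpha`` the reciprocal admixture fraction; ``n_sample`` the diploid
    sample size per population; ``threshold`` the rare/common cutoff applied
    to sample frequencies.
    """

    N: int = 20_000
    t_over_2n: float = 0.05
    alpha: float = 0.0
    n_sample: int = 100
    threshold: Fraction = Fraction(1, 20)

    def __post_init__(self) -> None:
        if self.N < 1 or self.n_sample < 1:
            raise ValueError("N and n_sample must be >= 1")
        if self.t_over_2n < 0:
            raise ValueError("scaled divergence time must be >= 0")
        if not 0 <= self.alpha <= 0.5:
            raise ValueError("alpha must lie in [0, 0.5]")
        object.__setattr__(self, "threshold", _as_fraction(self.threshold))

    @property
    def t_generations(self) -> float:
        """Divergence time in generations (4N per unit of scaled time)."""
        return self.t_over_2n * 4 * self.N

    @property
    def rare_count_max(self) -> int:
        """Largest sample count still coded 'R' (count <= threshold * 2n)."""
        thr = self.threshold
        return (thr.numerator * 2 * self.n_sample) // thr.denominator


@dataclass(frozen=True)
class TwoPopCodeDistribution:
    """Proportions of segregating sites over the eight two-population codes."""

    proportions: dict[str, float]

    def __post_init__(self) -> None:
        vals = np.array([self.proportions.get(c, 0.0) for c in TWO_POP_CODES])
        if np.any(vals < -1e-12):
            raise ValueError("negative code proportion")
        if abs(vals.sum() - 1.0) > 1e-6:
            raise ValueError(f"code proportions must sum to 1 (got {vals.sum()})")

    def __getitem__(self, code: str) -> float:
        return self.proportions.get(code, 0.0)

    def combined(self, *codes: str) -> float:
        return sum(self[c] for c in codes)

    def percent(self, *codes: str) -> float:
        return 100.0 * self.combined(*codes)


def _codes_from_joint_afs(afs: np.ndarray, params: SplitModelParams) -> TwoPopCodeDistribution:
    """Collapse a joint sample AFS onto the eight two-population codes."""
    m = 2 * params.n_sample
    if afs.shape != (m + 1, m + 1):
        raise ValueError("joint AFS shape does not match the sample size")
    cut = params.rare_count_max
    # letter class per count: 0 = u, 1 = R, 2 = C
    counts = np.arange(m + 1)
    cls = np.where(counts == 0, 0, np.where(counts <= cut, 1, 2))
    weights = np.zeros((3, 3))
    for a_cls in range(3):
        ia = cls == a_cls
        for b_cls in range(3):
            weights[a_cls, b_cls] = afs[np.ix_(ia, cls == b_cls)].sum()
    weights[0, 0] = 0.0  # pooled-absent class cannot occur among observed sites
    weights[2, 2] -= afs[m, m]  # fixed in the pooled sample: monomorphic, excluded
    letters = "uRC"
    props = {
        letters[a] + letters[b]: weights[a, b]
        for a in range(3)
        for b in range(3)
        if not (a == 0 and b == 0)
    }
    total = sum(props.values())
    return TwoPopCodeDistribution({k: v / total for k, v in props.items()})


def joint_sample_afs_coalescent(
    params: SplitModelParams,
    num_replicates: int = 4000,
    seed: int = 1,
) -> np.ndarray:
    """Expected joint sample AFS from replicate coalescent genealogies.

    Uses branch-length statistics (the exact expectation over mutation
    placement given each genealogy), summed over independent replicate
    trees, so the Monte Carlo noise comes only from the genealogies.
    The admixture pulse moves each sampled lineage to the other population
    with probability alpha immediately before sampling.
    """
    import msprime

    dem = msprime.Demography()
    dem.add_population(name="A", initial_size=params.N)
    dem.add_population(name="B", initial_size=params.N)
    dem.add_population(name="ANC", initial_size=params.N)
    if params.alpha > 0:
        dem.add_mass_migration(time=1e-6, source="A", dest="B", proportion=params.alpha)
        dem.add_mass_migration(time=2e-6, source="B", dest="A", proportion=params.alpha)
    t_split = max(params.t_generations, 3e-6)
    dem.add_population_split(time=t_split, derived=["A", "B"], ancestral="ANC")

    m = 2 * params.n_sample
    afs = np.zeros((m + 1, m + 1))
    reps = msprime.sim_ancestry(
        samples={"A": params.n_sample, "B": params.n_sample},
        demography=dem,
        num_replicates=num_replicates,
        random_seed=(int(seed) % (2**31 - 2)) + 1,
        ploidy=2,
    )
    for ts in reps:
        sets = [ts.samples(population=0), ts.samples(population=1)]
        afs += ts.allele_frequency_spectrum(
            sample_sets=sets, mode="branch", polarised=True, span_normalise=False
        )
    return afs


def _wf_transition(H: int) -> np.ndarray:
    """Dense Wright-Fisher binomial transition matrix on counts 0..H."""
    j = np.arange(H + 1)
    return binom_dist.pmf(j[None, :], H, (j / H)[:, None])


def _matrix_power(P: np.ndarray, t: int) -> np.ndarray:
    K = np.eye(P.shape[0])
    M = P
    while t:
        if t & 1:
            K = K @ M
        t >>= 1
        if t:
            M = M @ M
    return K


def joint_population_afs_diffusion(params: SplitModelParams, grid: int = 1000):
    """Deterministic joint *population*-frequency measure on a drift grid.

    The continuum model is discretised as a Wright-Fisher population of
    ``grid`` genome copies (drift time rescaled to match the scaled
    divergence time). Returns (J, x) where J[a, b] is the expected density of
    sites with derived-allele counts (a, b) on the grid in populations (A, B)
    just before the admixture pulse, mixing the equilibrium standing
    variation of the ancestral population (spectrum 2/i) with the transient
    spectra of post-split private mutations.
    """
    H = int(grid)
    t_steps = int(round(2 * params.t_over_2n * H))  # 4N-unit time on a 2N-unit grid
    P = _wf_transition(H)
    i = np.arange(1, H)
    w = 2.0 / i

    if t_steps == 0:
        J = np.zeros((H + 1, H + 1))
        J[1:H, 1:H] += np.diag(w)
        return J, np.arange(H + 1) / H

    K = _matrix_power(P, t_steps)
    KI = K[1:H]  # start states 1..H-1
    J = (KI * w[:, None]).T @ KI

    # private post-split mutations: cumulative occupation of a new mutation
    acc = np.zeros(H + 1)
    cur = np.zeros(H + 1)
    cur[1] = 1.0
    for _ in range(t_steps):
        acc += cur
        cur = cur @ P
        cur[0] = 0.0  # extinct copies leave the spectrum; fixation stays
    J[:, 0] += acc  # new in A, absent in B
    J[0, :] += acc  # new in B, absent in A
    J[0, 0] = 0.0
    return J, np.arange(H + 1) / H


def expected_code_distribution(
    params: SplitModelParams,
    method: str = "coalescent",
    num_replicates: int = 4000,
    seed: int = 1,
    grid: int = 1000,
) -> TwoPopCodeDistribution:
    """Expected geographic-code abundances among pooled-sample segregating sites.

    ``method="coalescent"`` (default) averages exact branch-length joint AFS
    over replicate genealogies; ``method="diffusion"`` evaluates the same
    expectation deterministically on a Wright-Fisher transition-matrix grid.
    The two paths are independent implementations of the same model.
    """
    if method == "coalescent":
        afs = joint_sample_afs_coalescent(params, num_replicates=num_replicates, seed=seed)
        return _codes_from_joint_afs(afs, params)
    if method != "diffusion":
        raise ValueError("method must be 'coalescent' or 'diffusion'")

    J, x = joint_population_afs_diffusion(params, grid=grid)
    m = 2 * params.n_sample
    cut = params.rare_count_max
    a = params.alpha
    pA = (1 - a) * x[:, None] + a * x[None, :]
    pB = (1 - a) * x[None, :] + a * x[:, None]

    def class_probs(p):
        pu = (1 - p) ** m
        pr = binom_dist.cdf(cut, m, p) - pu
        return pu, pr, 1.0 - pu - pr

    Au, Ar, Ac = class_probs(pA)
    Bu, Br, Bc = class_probs(pB)
    classes = {"u": (Au, Bu), "R": (Ar, Br), "C": (Ac, Bc)}
    props: dict[str, float] = {}
    for la, (PA, _) in classes.items():
        for lb, (_, PB) in classes.items():
            if la == "u" and lb == "u":
                continue
            props[la + lb] = float((J * PA * PB).sum())
    props["CC"] -= float((J * pA**m * pB**m).sum())  # pooled-fixed sites excluded
    total = sum(props.values())
    return TwoPopCodeDistribution({k: v / total for k, v in props.items()})


# --------------------------------------------------------------------------
# Single-population Wright-Fisher drift: trajectories, extinction, growth
# --------------------------------------------------------------------------


def wright_fisher_trajectories(
    f0: float,
    generations: int,
    N: int,
    n_replicates: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Neutral Wright-Fisher frequency trajectories (replicates x time).

    Binomial reproduction over 2N genome copies; frequencies 0 and 1 are
    absorbing. Row r, column t is the frequency at generation t.
    """
    if not 0 <= f0 <= 1:
        raise ValueError("f0 must lie in [0, 1]")
    two_n = 2 * N
    rng = np.random.default_rng(seed)
    counts = np.full(n_replicates, int(round(f0 * two_n)), dtype=np.int64)
    out = np.empty((n_replicates, generations + 1))
    out[:, 0] = counts / two_n
    for t in range(1, generations + 1):
        seg = (counts > 0) & (counts < two_n)
        if seg.any():
            counts[seg] = rng.binomial(two_n, counts[seg] / two_n)
        out[:, t] = counts / two_n
    return out


def _wf_distribution_at(f0: float, t: int, N: int) -> np.ndarray:
    """Exact count distribution after t generations (transition-matrix path)."""
    two_n = 2 * N
    if two_n > 4000:
        raise ValueError("matrix method is intended for small N (2N <= 4000)")
    P = _wf_transition(two_n)
    v = np.zeros(two_n + 1)
    v[int(round(f0 * two_n))] = 1.0
    remaining = t
    # vector-matrix iteration; switch to matrix powers for very long horizons
    if t > 4 * two_n:
        K = _matrix_power(P, t)
        return v @ K
    for _ in range(remaining):
        v = v @ P
    return v


def extinction_probability(
    f0: float,
    t: int,
    N: int,
    method: str = "auto",
    n_replicates: int = 20_000,
    seed: int = 0,
) -> float:
    """Probability a neutral allele starting at frequency f0 is lost by generation t.

    ``method="matrix"`` uses the exact Wright-Fisher transition matrix (small
    N); ``"monte_carlo"`` simulates trajectories (standard error about
    sqrt(p(1-p)/n_replicates)); ``"auto"`` picks the matrix path when
    2N <= 2000. As t grows the value approaches 1 - f0, the complement of
    the neutral fixation probability.
    """
    if not 0 < f0 < 1:
        raise ValueError("f0 must lie strictly between 0 and 1")
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0:
        return 0.0
    if method == "auto":
        method = "matrix" if 2 * N <= 2000 else "monte_carlo"
    if method == "matrix":
        v = _wf_distribution_at(f0, t, N)
        return float(v[0])
    if method != "monte_carlo":
        raise ValueError("method must be 'auto', 'matrix' or 'monte_carlo'")
    traj = wright_fisher_trajectories(f0, t, N, n_replicates=n_replicates, seed=seed)
    return float((traj[:, -1] == 0).mean())


def conditional_mean_frequency(
    f0: float,
    t: int,
    N: int,
    method: str = "auto",
    n_replicates: int = 20_000,
    seed: int = 0,
) -> float:
    """E[f_t | f_t > 0] for a neutral Wright-Fisher allele.

    The unconditional mean stays at f0 (drift is a martingale), so
    conditioning on survival inflates the mean; for a new mutation
    (f0 = 1/2N) and t << 2N the conditional mean grows roughly linearly
    with t, which is what keeps young-mutation frequencies inside the
    triangular envelope f < t/2N.
    """
    if not 0 < f0 < 1:
        raise ValueError("f0 must lie strictly between 0 and 1")
    if t == 0:
        return f0
    if method == "auto":
        method = "matrix" if 2 * N <= 2000 else "monte_carlo"
    if method == "matrix":
        v = _wf_distribution_at(f0, t, N)
        f = np.arange(v.size) / (v.size - 1)
        alive = v[1:].sum()
        return float((v[1:] * f[1:]).sum() / alive)
    traj = wright_fisher_trajectories(f0, t, N, n_replicates=n_replicates, seed=seed)
    final = traj[:, -1]
    alive = final > 0
    if not alive.any():
        raise RuntimeError("no surviving replicates; increase n_replicates")
    return float(final[alive].mean())


def typical_frequency_change(f: float, delta_t: float, N: int) -> float:
    """Diffusion-scale standard deviation of drift: sqrt(f(1-f) dt / 2N).

    The heuristic magnitude of neutral frequency change over ``delta_t``
    generations in a population with 2N genome copies; e.g. an allele at 25%
    drifts by about +-10 percentage points over 0.05 x 2N generations,
    hence "likely in the (15%, 35%) interval".
    """
    if f in (0.0, 1.0):
        return 0.0
    if not 0 < f < 1:
        raise ValueError(f"frequency {f} outside [0, 1]")
    return math.sqrt(f * (1 - f) * delta_t / (2 * N))


def detection_power(f, n: int):
    """Probability of seeing an allele at least once in 2n sampled chromosomes.

    Binomial sampling: 1 - (1 - f)^(2n). With a 404-diploid sample, an
    allele at 0.2% frequency is detected with probability ~0.80.
    """
    f = np.asarray(f, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("frequency must lie in [0, 1]")
    if n < 1:
        raise ValueError("sample size must be >= 1")
    out = 1.0 - (1.0 - f) ** (2 * n)
    return float(out) if out.ndim == 0 else out
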