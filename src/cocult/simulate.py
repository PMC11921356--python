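"""Synthetic cross-feeding consortium simulator and planted-effect generators.

Every input the pipeline consumes can be generated here with known ground
truth:

* :func:`simulate_consortium` integrates a minimal Monod-kinetics model of
  two strains on one carbon source C with one secreted metabolite pool M
  (standing in for the branched-chain amino acids): the donor A grows on C
  and secretes M in proportion to its growth; the partner B grows on C
  and/or on M.  Observed OD600 is A + B plus truncated Gaussian noise.
* :func:`generate_growth_dataset` turns a list of per-(pair, carbon)
  scenarios into a replicated plate-reader dataset with per-triad true
  interaction labels.  Positive scenarios are cross-feeding; negative ones
  are interference (a coculture-specific growth-rate penalty on one
  strain); neutral ones are independent growth or joint non-growth.
* :func:`pattern_fixture` is a deterministic 6-pair x 14-carbon
  dataset whose composition matches the published experiment: 33
  positive-structured combinations (28 with a single utilizing strain, 5
  with both), 7 negative-structured (4 single, 3 both), 44 neutral.
* :func:`generate_expression_counts` and
  :func:`generate_recruitment_matrix` plant known differential-expression
  effects and rank correlations into count matrices.

All generators are reproducible: the same seed gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .expression import COCULTURE, MONOCULTURE, CountMatrix
from .abundance import RecruitmentMatrix
from .growth import GrowthCurve, GrowthDataset
from .interactions import NEGATIVE, NEUTRAL, POSITIVE

DEFAULT_TIMES = (1.0, 3.0, 5.0, 7.0, 9.0)

#: Canonical kinetics of a strain that utilizes the carbon source.
MU_USE = 2.0      # /day
K_HALF = 0.1      # g/L
YIELD_OD = 0.15   # OD per g/L

#: Cross-feeding defaults (positive scenarios).
GAMMA = 2.0       # g/L of M secreted per OD unit of donor growth
MU_M = 2.5        # /day, recipient growth on M
K_M = 0.1         # g/L
YIELD_M = 0.5     # OD per g/L of M

#: Interference default (negative scenarios): coculture-specific
#: multiplier on the penalized strain's maximum growth rate.
CO_PENALTY = 0.15

POSITIVE_SINGLE = "positive_single"
POSITIVE_BOTH = "positive_both"
NEGATIVE_SINGLE = "negative_single"
NEGATIVE_BOTH = "negative_both"
NEUTRAL_KIND = "neutral"

_LABEL_OF_KIND = {
    POSITIVE_SINGLE: POSITIVE,
    POSITIVE_BOTH: POSITIVE,
    NEGATIVE_SINGLE: NEGATIVE,
    NEGATIVE_BOTH: NEGATIVE,
    NEUTRAL_KIND: NEUTRAL,
}


class IntegrationError(RuntimeError):
    """Raised when the fixed-step integrator produces a non-finite state."""


@dataclass(frozen=True)
class ConsortiumModelParams:
    """Parameters of the two-strain cross-feeding Monod model.

    Rates are per day, substrate concentrations g/L, biomass in OD600
    units.  ``gamma`` couples donor growth to metabolite secretion; the
    yields convert consumed substrate into biomass.  ``C0`` defaults to
    1 g/L (a 0.1% w/v carbon source); the total inoculum defaults to
    0.005 OD, split between the strains in coculture.
    """

    mu_max_AC: float = MU_USE
    mu_max_BC: float = 0.0
    mu_max_BM: float = 0.0
    K_AC: float = K_HALF
    K_BC: float = K_HALF
    K_BM: float = K_M
    Y_AC: float = YIELD_OD
    Y_BC: float = YIELD_OD
    Y_BM: float = YIELD_M
    gamma: float = 0.0
    C0: float = 1.0
    A0: float = 0.005
    B0: float = 0.0
    od_noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        for name in ("mu_max_AC", "mu_max_BC", "mu_max_BM", "K_AC", "K_BC",
                     "K_BM", "Y_AC", "Y_BC", "Y_BM", "gamma", "od_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.C0 <= 0:
            raise ValueError("C0 must be > 0")
        if self.A0 <= 0:
            raise ValueError("A0 must be > 0")
        if self.B0 < 0:
            raise ValueError("B0 must be >= 0")


@dataclass
class Trajectory:
    """Dense model solution plus noisy OD observations at sampling times.

    ``U`` is the cumulative partner growth attributable to the carbon
    source (not to M), used for mass-balance diagnostics:
    ``(A - A0)/Y_AC + U/Y_BC == C0 - C`` up to integration error.
    """

    t: np.ndarray
    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    M: np.ndarray
    U: np.ndarray
    times: np.ndarray
    od_true: np.ndarray      # A + B at the sampling times
    od_observed: np.ndarray  # od_true + truncated Gaussian noise

    def at(self, time: float) -> dict:
        i = int(np.argmin(np.abs(self.t - time)))
        return {k: float(getattr(self, k)[i]) for k in ("A", "B", "C", "M", "U")}


def _monod(mu_max: float, S: float, K: float) -> float:
    if S <= 0:
        return 0.0
    return mu_max * S / (K + S)


def simulate_consortium(params: ConsortiumModelParams, times=DEFAULT_TIMES,
                        include_B: bool = True, step: float = 0.01,
                        rng=None) -> Trajectory:
    """Integrate the consortium model with classical fixed-step RK4.

    The state is (A, B, C, M) with Monod uptake::

        dA/dt = mu_AC(C) * A
        dB/dt = [mu_BC(C) + mu_BM(M)] * B
        dC/dt = -(1/Y_AC) mu_AC(C) A - (1/Y_BC) mu_BC(C) B
        dM/dt = gamma * mu_AC(C) * A - (1/Y_BM) mu_BM(M) B

    State components are clipped at zero after each step.  ``include_B``
    False drops the partner (monoculture of A).  Observation noise is drawn
    from ``rng`` (or a generator seeded with ``params.seed``), so the
    result is deterministic given the seed.
    """
    if step <= 0 or step > 0.01 + 1e-12:
        raise ValueError("step must be positive and <= 0.01 day")
    times = np.asarray(times, dtype=float)
    if times.size == 0 or times[0] < 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be increasing and start >= 0")
    p = params
    b0 = p.B0 if include_B else 0.0

    def rhs(state):
        A, B, C, M, _ = state
        mu_a = _monod(p.mu_max_AC, C, p.K_AC)
        mu_bc = _monod(p.mu_max_BC, C, p.K_BC) if include_B else 0.0
        mu_bm = _monod(p.mu_max_BM, M, p.K_BM) if include_B else 0.0
        dC = -mu_a * A / p.Y_AC - (mu_bc * B / p.Y_BC if p.Y_BC > 0 else 0.0)
        dM = p.gamma * mu_a * A - (mu_bm * B / p.Y_BM if p.Y_BM > 0 else 0.0)
        return (mu_a * A, (mu_bc + mu_bm) * B, dC, dM, mu_bc * B)

    t_end = float(times[-1])
    n_steps = max(1, int(round(t_end / step)))
    h = t_end / n_steps
    grid = np.linspace(0.0, t_end, n_steps + 1)
    out = np.empty((n_steps + 1, 5))
    state = (p.A0, b0, p.C0, 0.0, 0.0)
    out[0] = state
    for i in range(n_steps):
        k1 = rhs(state)
        k2 = rhs(tuple(s + 0.5 * h * k for s, k in zip(state, k1)))
        k3 = rhs(tuple(s + 0.5 * h * k for s, k in zip(state, k2)))
        k4 = rhs(tuple(s + h * k for s, k in zip(state, k3)))
        state = tuple(
            max(0.0, s + h / 6.0 * (a + 2 * b + 2 * c + d))
            for s, a, b, c, d in zip(state, k1, k2, k3, k4)
        )
        if any(math.isnan(s) or math.isinf(s) for s in state):
            raise IntegrationError(f"non-finite state at t={grid[i + 1]:.3f}")
        out[i + 1] = state

    idx = np.rint(times / h).astype(int)
    od_true = out[idx, 0] + out[idx, 1]
    if rng is None:
        rng = np.random.default_rng(p.seed)
    noise = rng.normal(0.0, p.od_noise_sd, size=od_true.size) if p.od_noise_sd > 0 else 0.0
    od_observed = np.maximum(0.0, od_true + noise)
    return Trajectory(t=grid, A=out[:, 0], B=out[:, 1], C=out[:, 2],
                      M=out[:, 3], U=out[:, 4], times=times,
                      od_true=od_true, od_observed=od_observed)


@dataclass(frozen=True)
class ScenarioSpec:
    """Ground-truth construction rule for one (pair, carbon) combination.

    ``donor`` names the strain cast in the A role of the ODE (the carbon
    utilizer/secretor in positive scenarios, the penalized strain in
    negative ones).  ``uses`` are the intended monoculture utilization
    flags; ``mono_overrides`` may pin per-strain Monod parameters
    (``mu``, ``K``, ``Y``) that must be consistent across scenarios
    sharing a monoculture.
    """

    kind: str
    pair: tuple
    carbon: str
    donor: str
    uses: dict
    mono_overrides: dict = field(default_factory=dict)
    co_penalty: float = CO_PENALTY
    gamma: float = GAMMA

    def __post_init__(self):
        if self.kind not in _LABEL_OF_KIND:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if len(self.pair) != 2 or self.donor not in self.pair:
            raise ValueError("donor must be one of the pair")
        a, b = self.pair
        partner = b if self.donor == a else a
        use_d, use_p = self.uses[self.donor], self.uses[partner]
        expect = {
            POSITIVE_SINGLE: (True, False),
            POSITIVE_BOTH: (True, True),
            NEGATIVE_SINGLE: (True, False),
            NEGATIVE_BOTH: (True, True),
        }
        if self.kind in expect and (use_d, use_p) != expect[self.kind]:
            raise ValueError(
                f"{self.kind} requires donor/partner utilization {expect[self.kind]}, "
                f"got ({use_d}, {use_p})"
            )

    @property
    def true_label(self) -> str:
        return _LABEL_OF_KIND[self.kind]

    @property
    def true_case(self) -> str:
        if self.kind == NEUTRAL_KIND:
            return "not_applicable"
        n_use = sum(bool(self.uses[s]) for s in self.pair)
        return {2: "both_use", 1: "single_use", 0: "neither_use"}[n_use]


def scenario(kind: str, pair, carbon, donor=None, uses=None, **kwargs) -> ScenarioSpec:
    """Convenience constructor filling canonical utilization flags."""
    pair = tuple(sorted(pair))
    donor = donor or pair[0]
    partner = pair[1] if donor == pair[0] else pair[0]
    if uses is None:
        default_uses = {
            POSITIVE_SINGLE: {donor: True, partner: False},
            POSITIVE_BOTH: {donor: True, partner: True},
            NEGATIVE_SINGLE: {donor: True, partner: False},
            NEGATIVE_BOTH: {donor: True, partner: True},
            NEUTRAL_KIND: {donor: False, partner: False},
        }[kind]
        uses = default_uses
    return ScenarioSpec(kind=kind, pair=pair, carbon=str(carbon), donor=donor,
                        uses=dict(uses), **kwargs)


@dataclass
class SimulatedDataset:
    """A generated growth dataset plus its per-(pair, carbon) ground truth."""

    dataset: GrowthDataset
    ground_truth: dict  # (pair, carbon) -> {"label": ..., "case": ..., "uses": ...}
    seed: int


def _resolve_mono_params(scenarios) -> dict:
    """Per-(strain, carbon) monoculture kinetics implied by the scenarios.

    Conflicting utilization flags or parameter overrides for a shared
    monoculture are design errors.
    """
    mono: dict = {}
    for sc in scenarios:
        for strain in sc.pair:
            key = (strain, sc.carbon)
            ov = sc.mono_overrides.get(strain, {})
            entry = {
                "use": sc.uses[strain],
                "mu": ov.get("mu", MU_USE if sc.uses[strain] else 0.0),
                "K": ov.get("K", K_HALF),
                "Y": ov.get("Y", YIELD_OD),
            }
            if key in mono and mono[key] != entry:
                raise ValueError(
                    f"inconsistent monoculture specification for {key}: "
                    f"{mono[key]} vs {entry}"
                )
            mono[key] = entry
    return mono


def generate_growth_dataset(scenarios, n_reps: int = 3, times=DEFAULT_TIMES,
                            seed: int = 0, od_noise_sd: float = 0.01,
                            inoculum_od: float = 0.005,
                            noise_floor: float = 0.05) -> SimulatedDataset:
    """Simulate a replicated growth experiment from per-triad scenarios.

    Monocultures shared between pairs on the same carbon are simulated
    once from one parameter set; the coculture of each scenario reuses the
    same per-strain kinetics.  Replicates share the deterministic
    trajectory and differ only by independent observation noise.
    """
    scenarios = list(scenarios)
    if not scenarios:
        raise ValueError("no scenarios given")
    keys = [(sc.pair, sc.carbon) for sc in scenarios]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (pair, carbon) scenario")
    rng = np.random.default_rng(seed)
    mono = _resolve_mono_params(scenarios)

    curves = []

    def observe(traj, strains, carbon):
        for rep in range(1, n_reps + 1):
            noise = rng.normal(0.0, od_noise_sd, size=len(traj.times))
            od = np.maximum(0.0, traj.od_true + noise)
            curves.append(GrowthCurve(strains=strains, carbon=carbon,
                                      replicate=rep, times=tuple(traj.times),
                                      od=tuple(od)))

    for (strain, carbon), kin in sorted(mono.items()):
        p = ConsortiumModelParams(
            mu_max_AC=kin["mu"], K_AC=kin["K"], Y_AC=kin["Y"],
            A0=inoculum_od, B0=0.0, od_noise_sd=0.0,
        )
        observe(simulate_consortium(p, times, include_B=False), {strain}, carbon)

    ground_truth = {}
    for sc in sorted(scenarios, key=lambda s: (s.pair, s.carbon)):
        donor = sc.donor
        partner = sc.pair[1] if donor == sc.pair[0] else sc.pair[0]
        kd = mono[(donor, sc.carbon)]
        kp = mono[(partner, sc.carbon)]
        positive = sc.kind in (POSITIVE_SINGLE, POSITIVE_BOTH)
        negative = sc.kind in (NEGATIVE_SINGLE, NEGATIVE_BOTH)
        p = ConsortiumModelParams(
            mu_max_AC=kd["mu"] * (sc.co_penalty if negative else 1.0),
            K_AC=kd["K"], Y_AC=kd["Y"],
            mu_max_BC=kp["mu"], K_BC=kp["K"], Y_BC=kp["Y"],
            mu_max_BM=MU_M if positive else 0.0, K_BM=K_M, Y_BM=YIELD_M,
            gamma=sc.gamma if positive else 0.0,
            A0=inoculum_od / 2, B0=inoculum_od / 2, od_noise_sd=0.0,
        )
        observe(simulate_consortium(p, times, include_B=True),
                set(sc.pair), sc.carbon)
        ground_truth[(sc.pair, sc.carbon)] = {
            "label": sc.true_label, "case": sc.true_case, "uses": dict(sc.uses),
        }

    ds = GrowthDataset(curves=curves, inoculum_od=inoculum_od,
                       noise_floor=noise_floor)
    return SimulatedDataset(dataset=ds, ground_truth=ground_truth, seed=seed)


# --- the deterministic published-pattern fixture ---------------------------

FIXTURE_STRAINS = ("M597", "S1616", "T6124", "W002")
FIXTURE_CARBONS = (
    "D-arabinose", "D-arabitol", "D-gluconic acid", "D-maltose",
    "D-mannitol", "glycerol", "glycolic acid", "L-arabitol", "L-cysteine",
    "L-glutamic acid", "L-histidine", "L-rhamnose", "L-threonine",
    "pyruvic acid",
)

# Per-carbon templates over role slots (r1..r4).  Interaction labels hold
# with certainty because every pair left neutral involves no strain that
# grows on the carbon (all its group means sit below the noise floor).
#   P2: r1, r2 utilize; (r1,r2) cross-feed with both growing, r1 and r2
#       each cross-feed the two non-utilizers -> 1 both-use + 4 single-use
#       positives.
#   M1: r1, r2 utilize; (r1,r2) both-use positive, r1 feeds r3 and r4,
#       r2 is penalized against r3 and r4 -> 2 single positives +
#       1 both positive + 2 single negatives.
#   M2: r1 (high-yield), r2 utilize; (r1,r2) both-use negative (r1
#       penalized), r1 and r2 each feed one non-utilizer and r2 also
#       feeds the other -> 4 single positives + 1 both negative.
#   Z:  nobody utilizes; 6 neutral pairs.
_TEMPLATES = {
    "P2": [(POSITIVE_BOTH, 0, 1), (POSITIVE_SINGLE, 0, 2), (POSITIVE_SINGLE, 0, 3),
           (POSITIVE_SINGLE, 1, 2), (POSITIVE_SINGLE, 1, 3)],
    "M1": [(POSITIVE_BOTH, 0, 1), (POSITIVE_SINGLE, 0, 2), (POSITIVE_SINGLE, 0, 3),
           (NEGATIVE_SINGLE, 1, 2), (NEGATIVE_SINGLE, 1, 3)],
    "M2": [(NEGATIVE_BOTH, 0, 1), (POSITIVE_SINGLE, 0, 2), (POSITIVE_SINGLE, 0, 3),
           (POSITIVE_SINGLE, 1, 2), (POSITIVE_SINGLE, 1, 3)],
    "Z": [],
}

_FIXTURE_PLAN = {
    "D-arabinose": "P2",
    "D-arabitol": "P2",
    "D-gluconic acid": "P2",
    "D-mannitol": "M1",
    "L-rhamnose": "M1",
    "glycerol": "M2",
    "L-glutamic acid": "M2",
    "pyruvic acid": "M2",
    # the remaining six carbons carry no interactions
    "D-maltose": "Z",
    "glycolic acid": "Z",
    "L-arabitol": "Z",
    "L-cysteine": "Z",
    "L-histidine": "Z",
    "L-threonine": "Z",
}


def pattern_fixture(seed: int = 1, od_noise_sd: float = 0.005) -> SimulatedDataset:
    """Deterministic 6-pair x 14-carbon dataset matching the published
    interaction composition.

    Of the 84 (pair, carbon) combinations, 33 are positive-structured (28
    single-utilizer, 5 both-utilizer), 7 negative-structured (4 single, 3
    both) and 44 neutral.  Effect sizes are large relative to the
    observation noise (sd 0.005 OD), so the labels are recovered with
    certainty by the default analysis configuration.
    """
    scenarios = []
    for ci, carbon in enumerate(FIXTURE_CARBONS):
        template = _FIXTURE_PLAN[carbon]
        roles = tuple(FIXTURE_STRAINS[(ci + k) % 4] for k in range(4))
        users = set()
        specs = []
        for kind, di, pi in _TEMPLATES[template]:
            donor, partner = roles[di], roles[pi]
            users.add(donor)
            if kind in (POSITIVE_BOTH, NEGATIVE_BOTH):
                users.add(partner)
            specs.append((kind, donor, partner))
        # high-yield donor makes the both-use negative detectable despite
        # OD additivity (the coculture tracks the low-yield partner)
        y_override = {}
        if template == "M2":
            y_override = {roles[0]: {"mu": MU_USE, "K": K_HALF, "Y": 0.35}}
        covered = set()
        for kind, donor, partner in specs:
            uses = {donor: True, partner: partner in users}
            ov = {s: y_override[s] for s in (donor, partner) if s in y_override}
            scenarios.append(scenario(kind, (donor, partner), carbon,
                                      donor=donor, uses=uses, mono_overrides=ov))
            covered.add(tuple(sorted((donor, partner))))
        from itertools import combinations
        for pair in combinations(roles, 2):
            key = tuple(sorted(pair))
            if key in covered:
                continue
            uses = {s: s in users for s in key}
            ov = {s: y_override[s] for s in key if s in y_override}
            scenarios.append(scenario(NEUTRAL_KIND, key, carbon,
                                      uses=uses, mono_overrides=ov))
    return generate_growth_dataset(scenarios, n_reps=3, times=DEFAULT_TIMES,
                                   seed=seed, od_noise_sd=od_noise_sd)


def generate_null_dataset(n_triads: int = 500, mean_od: float = 0.2,
                          sd: float = 0.01, n_reps: int = 3,
                          seed: int = 0) -> GrowthDataset:
    """No-interaction null: coculture and both monocultures of every triad
    drawn from the same normal distribution (truncated at 0).

    Each triad uses its own strain pair and carbon label, so the pooled
    FDR family has two genuinely null comparisons per triad.
    """
    rng = np.random.default_rng(seed)
    curves = []
    for i in range(n_triads):
        a, b, carbon = f"A{i}", f"B{i}", f"c{i}"
        for strains in ({a}, {b}, {a, b}):
            for rep in range(1, n_reps + 1):
                od = max(0.0, rng.normal(mean_od, sd))
                curves.append(GrowthCurve(strains=strains, carbon=carbon,
                                          replicate=rep, times=(1.0,), od=(od,)))
    return GrowthDataset(curves=curves)


# --- expression and recruitment generators ---------------------------------

@dataclass
class SimulatedExpression:
    counts: CountMatrix
    planted_up: list
    planted_down: list
    seed: int


def generate_expression_counts(n_genes: int = 2000, n_planted_up: int = 50,
                               n_planted_down: int = 0, effect_fold: float = 8.0,
                               dispersion: float = 0.05, n_reps: int = 3,
                               seed: int = 0) -> SimulatedExpression:
    """Negative-binomial count matrix with planted expression effects.

    Baseline per-gene mean counts are log-uniform on [5, 500]; planted
    genes are scaled by ``effect_fold`` (up) or its reciprocal (down) in
    the coculture condition.  ``dispersion`` is the NB overdispersion
    (variance = m + dispersion * m^2); zero is the noise-free limit
    (counts are the rounded means).  Gene lengths are uniform on
    [300, 3000] bp and totals are column sums.
    """
    if n_planted_up + n_planted_down > n_genes:
        raise ValueError("planted genes exceed n_genes")
    if effect_fold <= 1:
        raise ValueError("effect_fold must be > 1")
    rng = np.random.default_rng(seed)
    base = np.exp(rng.uniform(np.log(5.0), np.log(500.0), size=n_genes))
    lengths = rng.integers(300, 3001, size=n_genes)
    up = list(range(n_planted_up))
    down = list(range(n_planted_up, n_planted_up + n_planted_down))

    mean_co = base.copy()
    mean_co[up] *= effect_fold
    mean_co[down] /= effect_fold

    def draw(mean, n):
        out = np.empty((n_genes, n), dtype=np.int64)
        for j in range(n):
            if dispersion <= 0:
                out[:, j] = np.rint(mean)
            else:
                r = 1.0 / dispersion
                out[:, j] = rng.negative_binomial(r, r / (r + mean))
        return out

    counts = np.hstack([draw(mean_co, n_reps), draw(base, n_reps)])
    samples = [f"co_{i+1}" for i in range(n_reps)] + [f"mono_{i+1}" for i in range(n_reps)]
    condition = {s: (COCULTURE if s.startswith("co_") else MONOCULTURE) for s in samples}
    cm = CountMatrix(gene_ids=[f"g{i:05d}" for i in range(n_genes)],
                     gene_lengths=lengths, sample_ids=samples,
                     condition=condition, counts=counts)
    return SimulatedExpression(counts=cm, planted_up=[cm.gene_ids[i] for i in up],
                               planted_down=[cm.gene_ids[i] for i in down], seed=seed)


def generate_recruitment_matrix(n_samples: int = 20, n_strains: int = 4,
                                base_profile=None, rank_agreement: float = 0.9,
                                depth_range=(1_200_000, 3_000_000),
                                spread: float = 0.8,
                                seed: int = 0) -> RecruitmentMatrix:
    """Recruitment counts with a planted pairwise rank correlation.

    A per-sample community factor drives all strains through a Gaussian
    copula whose latent Pearson correlation ``r = 2 sin(pi rho / 6)`` is
    chosen so that pairwise Spearman correlation equals ``rank_agreement``
    in expectation.  Strain relative abundances are log-normal around
    ``base_profile`` (default ~0.5% each, the rest of the library being
    unrecruited reads); counts are multinomial at a per-sample depth drawn
    from ``depth_range``.
    """
    if n_samples < 4:
        raise ValueError("need n_samples >= 4")
    if not 0 <= rank_agreement <= 1:
        raise ValueError("rank_agreement must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if base_profile is None:
        base_profile = np.full(n_strains, 0.005)
    base_profile = np.asarray(base_profile, dtype=float)
    if base_profile.size != n_strains or np.any(base_profile <= 0):
        raise ValueError("base_profile must hold a positive weight per strain")
    if base_profile.sum() >= 0.5:
        raise ValueError("strains must stay a minority of the library")

    r = 2.0 * math.sin(math.pi * rank_agreement / 6.0)
    counts = np.empty((n_samples, n_strains), dtype=np.int64)
    other = np.empty(n_samples, dtype=np.int64)
    for i in range(n_samples):
        z = rng.normal()
        eps = rng.normal(size=n_strains)
        u = math.sqrt(r) * z + np.sqrt(1.0 - r) * eps
        w = base_profile * np.exp(spread * u - 0.5 * spread**2)
        w = np.minimum(w, 0.1)  # cap a runaway strain at 10% of the library
        depth = int(rng.integers(depth_range[0], depth_range[1] + 1))
        probs = np.append(w, 1.0 - w.sum())
        draw = rng.multinomial(depth, probs)
        counts[i] = draw[:n_strains]
        other[i] = draw[n_strains]
    return RecruitmentMatrix(
        sample_ids=[f"s{i+1:03d}" for i in range(n_samples)],
        strain_ids=[f"strain_{chr(65 + i)}" for i in range(n_strains)],
        counts=counts, other_counts=other,
    )
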