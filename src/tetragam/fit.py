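"""Per-locus maximum-likelihood estimation of the segregation mixture.

For each pairing-scenario equivalence class the multinomial log-likelihood of
the observed gamete-class counts is maximized over (tau, beta) by a
deterministic coarse grid followed by local refinement, and the best scenario
is retained.  The fitted model is compared against full tetrasomy (tau = 1)
with a likelihood-ratio test whose null distribution is the boundary mixture
(1/2) chi2_0 + (1/2) chi2_1.

Because the class probabilities are linear in tau and tau*beta,

    P(class) = d + tau (c - d) + tau beta (r - c),

with d, c, r the disomic, random-pairing and double-reduction mode
distributions, each scenario is represented by three fixed coefficient
vectors and likelihood evaluations are cheap vector operations.  beta is
structurally non-identifiable when every double-reduction product coincides
with a class already producible by random pairing or disomy (e.g. the
di-allelic duplex AABB, where AA arises from both); this is detected
symbolically and beta is then fixed at 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Hashable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2 as chi2_dist

from .inference import LocusCounts
from .model import (
    Allele,
    GameteClass,
    PairingScenario,
    SegregationParams,
    TetraploidGenotype,
    disomic_distribution,
    double_reduction_distribution,
    enumerate_scenarios,
    gamete_class,
    random_pairing_distribution,
)

__all__ = [
    "FitResult",
    "DistortionResult",
    "LocusModel",
    "loglik",
    "fit_locus",
    "fit_duplex",
    "compound_lrt_pvalue",
    "lrt_vs_tetrasomic",
    "deviance_profile",
    "allele_distortion_test",
]

_TIE_TOL = 1e-9


@dataclass
class FitResult:
    """Per-locus fit of the disomic/tetrasomic/double-reduction mixture."""

    locus_name: str
    scenario: PairingScenario
    tau_hat: float
    beta_hat: Optional[float]
    beta_identifiable: bool
    loglik: float
    loglik_tetrasomic: float
    deviance_G: float
    lrt: float
    p_value: float
    preferential_direction: str  # "homologous" | "heterologous" | "none"
    tie: bool
    n: int
    dr_ceiling_exceeded: bool = False

    @property
    def params(self) -> SegregationParams:
        return SegregationParams(self.tau_hat, self.beta_hat or 0.0)


@dataclass
class DistortionResult:
    """Chi-square goodness-of-fit of pooled allele counts to parental dosage."""

    locus_name: str
    chi2: float
    df: int
    p_value: float
    allele_counts: Dict[Allele, int]
    expected_counts: Dict[Allele, float]


class _ScenarioModel:
    """Coefficient vectors (d, c, r) for one scenario over a fixed class list."""

    def __init__(self, classes: List[Hashable], d: np.ndarray, c: np.ndarray,
                 r: np.ndarray, scenario: PairingScenario, eq_id: int,
                 multiplicity: int):
        self.classes = classes
        self.d = d
        self.c = c
        self.r = r
        self.scenario = scenario
        self.eq_id = eq_id
        self.multiplicity = multiplicity
        # beta is identifiable iff some class is reachable by double reduction
        # only (zero disomic and random-pairing probability).
        self.beta_identifiable = bool(np.any((r > 0) & (c == 0) & (d == 0)))

    def probs(self, tau: float, beta: float) -> np.ndarray:
        return self.d + tau * (self.c - self.d) + tau * beta * (self.r - self.c)


class LocusModel:
    """All scenario equivalence classes of a genotype, ready for fitting.

    ``merge`` optionally maps gamete classes to coarser observable labels
    (e.g. visible-allele signatures when dosage is unavailable under a
    null-allele constitution); probabilities of merged classes are summed.
    """

    def __init__(
        self,
        genotype: TetraploidGenotype,
        merge: Optional[Callable[[GameteClass], Hashable]] = None,
        extra_labels: Sequence[Hashable] = (),
    ):
        self.genotype = genotype
        self.merge = merge
        relabel = (lambda cls: merge(cls)) if merge else (lambda cls: cls)

        def merged(dist) -> Dict[Hashable, float]:
            out: Dict[Hashable, float] = {}
            for cls, p in dist.items():
                lbl = relabel(cls)
                out[lbl] = out.get(lbl, 0.0) + float(p)
            return out

        scen = enumerate_scenarios(genotype)
        c_map = merged(random_pairing_distribution(genotype))
        r_map = merged(double_reduction_distribution(genotype))
        d_maps = {}
        reps: Dict[int, Tuple[PairingScenario, int]] = {}
        for scenario, eq_id in scen:
            if eq_id not in reps:
                reps[eq_id] = (scenario, 1)
                d_maps[eq_id] = merged(disomic_distribution(genotype, scenario))
            else:
                s, m = reps[eq_id]
                reps[eq_id] = (s, m + 1)

        labels = set(c_map) | set(r_map) | set(extra_labels)
        for d_map in d_maps.values():
            labels |= set(d_map)
        self.classes: List[Hashable] = sorted(labels)
        index = {lbl: i for i, lbl in enumerate(self.classes)}

        def vec(mapping: Dict[Hashable, float]) -> np.ndarray:
            v = np.zeros(len(self.classes))
            for lbl, p in mapping.items():
                v[index[lbl]] = p
            return v

        c_vec, r_vec = vec(c_map), vec(r_map)
        self.scenarios: List[_ScenarioModel] = [
            _ScenarioModel(self.classes, vec(d_maps[eq_id]), c_vec, r_vec,
                           scenario, eq_id, mult)
            for eq_id, (scenario, mult) in sorted(reps.items())
        ]
        self.index = index

    def counts_vector(self, counts: LocusCounts) -> np.ndarray:
        y = np.zeros(len(self.classes))
        for cls, k in counts.counts.items():
            lbl = self.merge(tuple(cls)) if self.merge else tuple(cls)
            if lbl not in self.index:
                if k > 0:
                    raise ValueError(
                        f"{counts.locus_name}: observed class {cls!r} has zero "
                        "probability under every parameter value for this genotype"
                    )
                continue
            y[self.index[lbl]] += k
        return y


def _loglik_vec(y: np.ndarray, p: np.ndarray) -> float:
    mask = y > 0
    if np.any(p[mask] <= 0):
        return -math.inf
    return float(np.dot(y[mask], np.log(p[mask])))


def loglik(
    counts: LocusCounts,
    genotype: TetraploidGenotype,
    scenario: PairingScenario,
    params: SegregationParams,
    merge: Optional[Callable[[GameteClass], Hashable]] = None,
) -> float:
    """Multinomial log-likelihood (constant term omitted); -inf is valid."""
    model = LocusModel(genotype, merge=merge)
    try:
        y = model.counts_vector(counts)
    except ValueError:
        return -math.inf
    for sm in model.scenarios:
        if sm.scenario.pairs == scenario.pairs or _same_scenario(model, sm, scenario):
            return _loglik_vec(y, sm.probs(params.tau, params.beta))
    raise ValueError("scenario does not belong to this genotype")


def _same_scenario(model: LocusModel, sm: _ScenarioModel,
                   scenario: PairingScenario) -> bool:
    """True if `scenario` falls in the equivalence class represented by `sm`."""
    for s, eq_id in enumerate_scenarios(model.genotype):
        if s.pairs == scenario.pairs:
            return eq_id == sm.eq_id
    return False


def _maximize_scenario(
    sm: _ScenarioModel, y: np.ndarray, grid_step: float, tol: float
) -> Tuple[float, float, float]:
    """Return (tau_hat, beta_hat, loglik) for one scenario model."""
    mask = y > 0
    yo = y[mask]
    d, c, r = sm.d[mask], sm.c[mask], sm.r[mask]

    tau_grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    if sm.beta_identifiable:
        beta_grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
        P = (d[None, None, :]
             + tau_grid[:, None, None] * (c - d)[None, None, :]
             + (tau_grid[:, None, None] * beta_grid[None, :, None])
             * (r - c)[None, None, :])
        with np.errstate(divide="ignore"):
            LL = np.where(P > 0, np.log(np.where(P > 0, P, 1.0)), -np.inf) @ yo
        it, ib = np.unravel_index(np.argmax(LL), LL.shape)
        t0, b0, ll0 = float(tau_grid[it]), float(beta_grid[ib]), float(LL[it, ib])

        def nll(x: np.ndarray) -> float:
            t = min(max(x[0], 0.0), 1.0)
            b = min(max(x[1], 0.0), 1.0)
            p = d + t * (c - d) + t * b * (r - c)
            if np.any(p <= 0):
                return 1e300
            return -float(np.dot(yo, np.log(p)))

        res = minimize(nll, x0=[t0, b0], method="Nelder-Mead",
                       bounds=[(0.0, 1.0), (0.0, 1.0)],
                       options={"xatol": tol, "fatol": 1e-12})
        if np.isfinite(res.fun) and -res.fun > ll0:
            return float(res.x[0]), float(res.x[1]), float(-res.fun)
        return t0, b0, ll0

    # beta structurally flat: fix beta = 0 and optimize in one dimension
    P = d[None, :] + tau_grid[:, None] * (c - d)[None, :]
    with np.errstate(divide="ignore"):
        LL = np.where(P > 0, np.log(np.where(P > 0, P, 1.0)), -np.inf) @ yo
    it = int(np.argmax(LL))
    t0, ll0 = float(tau_grid[it]), float(LL[it])

    def nll1(t: float) -> float:
        p = d + t * (c - d)
        if np.any(p <= 0):
            return 1e300
        return -float(np.dot(yo, np.log(p)))

    lo = max(0.0, t0 - grid_step)
    hi = min(1.0, t0 + grid_step)
    res = minimize_scalar(nll1, bounds=(lo, hi), method="bounded",
                          options={"xatol": tol})
    if np.isfinite(res.fun) and -res.fun > ll0:
        return float(res.x), 0.0, float(-res.fun)
    return t0, 0.0, ll0


def _tetrasomic_loglik(
    sm: _ScenarioModel, y: np.ndarray, beta_identifiable: bool, tol: float
) -> float:
    """Maximized log-likelihood under the tau = 1 null (beta re-optimized
    when identifiable, else fixed at 0)."""
    mask = y > 0
    yo = y[mask]
    c, r = sm.c[mask], sm.r[mask]
    if not beta_identifiable:
        return _loglik_vec(y, sm.c)

    def nll(b: float) -> float:
        p = c + b * (r - c)
        if np.any(p <= 0):
            return 1e300
        return -float(np.dot(yo, np.log(p)))

    res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": tol})
    return float(max(-res.fun, -nll(0.0)))


def _deviance(y: np.ndarray, p: np.ndarray, n: int) -> float:
    mask = y > 0
    e = n * p[mask]
    if np.any(e <= 0):
        return math.inf
    return float(2.0 * np.dot(y[mask], np.log(y[mask] / e)))


def compound_lrt_pvalue(lrt: float) -> float:
    """p-value of the LRT under the boundary null (1/2) chi2_0 + (1/2) chi2_1."""
    if lrt <= 0:
        return 1.0
    return 0.5 * float(chi2_dist.sf(lrt, 1))


def lrt_vs_tetrasomic(fit: FitResult) -> Tuple[float, float]:
    """(LRT, p-value) of the fitted model against full tetrasomy (tau = 1)."""
    return fit.lrt, fit.p_value


def fit_locus(
    counts: LocusCounts,
    genotype: TetraploidGenotype,
    grid_step: float = 0.01,
    tol: float = 1e-6,
    merge: Optional[Callable[[GameteClass], Hashable]] = None,
    model: Optional[LocusModel] = None,
    scenario: Optional[PairingScenario] = None,
) -> FitResult:
    """Maximum-likelihood fit of (tau, beta) across pairing scenarios.

    Each scenario equivalence class is maximized independently; the scenario
    with the highest likelihood wins, ties (within 1e-9) being broken toward
    the homologous scenario and flagged.  Passing ``scenario`` restricts the
    fit to that scenario's equivalence class.  ``model`` may be passed to
    reuse a prebuilt :class:`LocusModel` across many fits of the same
    genotype.
    """
    if counts.n < 1:
        raise ValueError(f"{counts.locus_name}: no observed gametes")
    if model is None:
        model = LocusModel(genotype, merge=merge)
    y = model.counts_vector(counts)

    fitted = model.scenarios
    if scenario is not None:
        fitted = [sm for sm in fitted if _same_scenario(model, sm, scenario)]
        if not fitted:
            raise ValueError("scenario does not belong to this genotype")
    per_scenario = [
        (sm, *_maximize_scenario(sm, y, grid_step, tol)) for sm in fitted
    ]
    best_ll = max(item[3] for item in per_scenario)
    contenders = [item for item in per_scenario if item[3] >= best_ll - _TIE_TOL]
    # break ties toward the homologous scenario
    chosen = next(
        (it for it in contenders if it[0].scenario.is_homologous), contenders[0]
    )
    sm, tau_hat, beta_hat, ll = chosen
    tie = len(contenders) > 1
    all_tied = len(contenders) == len(per_scenario) and len(per_scenario) > 1
    if all_tied:
        direction = "none"
    else:
        direction = "homologous" if sm.scenario.is_homologous else "heterologous"

    ll_tet = _tetrasomic_loglik(sm, y, sm.beta_identifiable, tol)
    lrt = max(0.0, 2.0 * (ll - ll_tet))
    p_value = compound_lrt_pvalue(lrt)
    p_hat = sm.probs(tau_hat, beta_hat)
    result = FitResult(
        locus_name=counts.locus_name,
        scenario=sm.scenario,
        tau_hat=tau_hat,
        beta_hat=beta_hat if sm.beta_identifiable else None,
        beta_identifiable=sm.beta_identifiable,
        loglik=ll,
        loglik_tetrasomic=ll_tet,
        deviance_G=_deviance(y, p_hat, counts.n),
        lrt=lrt,
        p_value=p_value,
        preferential_direction=direction,
        tie=tie,
        n=counts.n,
        dr_ceiling_exceeded=(tau_hat * (beta_hat or 0.0)) > 1.0 / 6.0,
    )
    return result


def fit_duplex(
    counts: LocusCounts, genotype: Optional[TetraploidGenotype] = None
) -> FitResult:
    """Closed-form tau for a di-allelic duplex (AABB) locus, beta fixed at 0.

    Under the homologous scenario the class probabilities are
    {tau/6, 1 - tau/3, tau/6} for (AA, AB, BB), and the ML estimator is
    ``tau_hat = min(1, 3 (n_AA + n_BB) / n)``.
    """
    if counts.n < 1:
        raise ValueError(f"{counts.locus_name}: no observed gametes")
    alleles = sorted({a for cls in counts.counts for a in cls})
    if genotype is None:
        if len(alleles) == 1:
            alleles = alleles + alleles
        if len(alleles) != 2:
            raise ValueError(
                f"{counts.locus_name}: duplex fit needs exactly two alleles, "
                f"got {alleles}"
            )
        genotype = TetraploidGenotype.from_parents(
            counts.locus_name, (alleles[0], alleles[0]), (alleles[1], alleles[1])
        )
    mult = genotype.allele_multiplicity
    if len(mult) != 2 or set(mult.values()) != {2}:
        raise ValueError(f"{counts.locus_name}: genotype is not a di-allelic duplex")
    a, b = sorted(mult)
    n_hom = counts.counts.get(gamete_class(a, a), 0) + counts.counts.get(
        gamete_class(b, b), 0
    )
    tau_hat = min(1.0, 3.0 * n_hom / counts.n)

    model = LocusModel(genotype)
    sm = next(s for s in model.scenarios if s.scenario.is_homologous)
    y = model.counts_vector(counts)
    ll = _loglik_vec(y, sm.probs(tau_hat, 0.0))
    ll_tet = _loglik_vec(y, sm.c)
    lrt = max(0.0, 2.0 * (ll - ll_tet))
    return FitResult(
        locus_name=counts.locus_name,
        scenario=sm.scenario,
        tau_hat=tau_hat,
        beta_hat=None,
        beta_identifiable=False,
        loglik=ll,
        loglik_tetrasomic=ll_tet,
        deviance_G=_deviance(y, sm.probs(tau_hat, 0.0), counts.n),
        lrt=lrt,
        p_value=compound_lrt_pvalue(lrt),
        preferential_direction="homologous" if tau_hat < 1.0 else "none",
        tie=False,
        n=counts.n,
    )


def deviance_profile(
    counts: LocusCounts,
    genotype: TetraploidGenotype,
    scenario: Optional[PairingScenario] = None,
    tau_grid: Optional[Sequence[float]] = None,
    tol: float = 1e-6,
) -> List[Tuple[float, float]]:
    """Deviance G(tau) with beta profiled out at each grid point.

    ``G(tau) = 2 sum O ln(O / E(tau, beta_hat(tau)))`` with ``E = n P``;
    zero-count classes contribute 0.  Defaults to the homologous scenario and
    a 101-point grid on [0, 1].
    """
    if tau_grid is None:
        tau_grid = np.linspace(0.0, 1.0, 101)
    if any(t < 0 or t > 1 for t in tau_grid):
        raise ValueError("tau grid must lie within [0, 1]")
    model = LocusModel(genotype)
    if scenario is None:
        sm = next(s for s in model.scenarios if s.scenario.is_homologous)
    else:
        sm = next(
            (s for s in model.scenarios if _same_scenario(model, s, scenario)), None
        )
        if sm is None:
            raise ValueError("scenario does not belong to this genotype")
    y = model.counts_vector(counts)
    mask = y > 0
    yo = y[mask]
    d, c, r = sm.d[mask], sm.c[mask], sm.r[mask]
    out: List[Tuple[float, float]] = []
    for t in tau_grid:
        if sm.beta_identifiable and t > 0:

            def nll(b: float, t: float = t) -> float:
                p = d + t * (c - d) + t * b * (r - c)
                if np.any(p <= 0):
                    return 1e300
                return -float(np.dot(yo, np.log(p)))

            res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                                  options={"xatol": tol})
            b_hat = float(res.x) if res.fun <= nll(0.0) else 0.0
        else:
            b_hat = 0.0
        p = d + t * (c - d) + t * b_hat * (r - c)
        e = counts.n * p
        g = math.inf if np.any(e <= 0) else float(2.0 * np.dot(yo, np.log(yo / e)))
        out.append((float(t), g))
    return out


def allele_distortion_test(
    counts: LocusCounts, genotype: TetraploidGenotype
) -> DistortionResult:
    """Chi-square test of pooled gamete allele counts against parental dosage.

    Each gamete contributes two allele observations (nulls included when the
    constitution carries them); the expected count of allele ``a`` is
    ``n * dosage(a) / 2`` and the statistic is Pearson chi-square with
    ``k - 1`` degrees of freedom for ``k`` distinct parental alleles.
    """
    if counts.n < 1:
        raise ValueError(f"{counts.locus_name}: no observed gametes")
    mult = genotype.allele_multiplicity
    observed: Dict[Allele, int] = {a: 0 for a in mult}
    for cls, k in counts.counts.items():
        for a in cls:
            if a not in observed:
                raise ValueError(
                    f"{counts.locus_name}: observed allele {a!r} absent from "
                    f"parental constitution {genotype.alleles}"
                )
            observed[a] += k
    expected = {a: counts.n * m / 2.0 for a, m in mult.items()}
    stat = sum(
        (observed[a] - expected[a]) ** 2 / expected[a] for a in mult
    )
    df = len(mult) - 1
    p = float(chi2_dist.sf(stat, df)) if df > 0 else 1.0
    return DistortionResult(
        locus_name=counts.locus_name,
        chi2=float(stat),
        df=df,
        p_value=p,
        allele_counts=observed,
        expected_counts=expected,
    )
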