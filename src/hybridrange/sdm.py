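"""SDM fitting, TSS evaluation, family ensembles and consensus maps.

Four algorithms are fitted per species — GLM and GAM (regression family,
against 10,000 random background absences) and BRT and RF (machine-learning
family, against 10 replicate exclusion-radius pseudo-absence draws). Each
fit is scored by repeated 80/20 split-sample TSS; within each family the
member projections are averaged with TSS weights, binarised at the
threshold that maximises TSS on the family's pooled calibration data, and
the two family binaries are AND-combined into a conservative consensus
range map.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from statsmodels.gam.api import BSplines, GLMGam

from .grids import (
    BinaryMap,
    ClimateStack,
    DomainError,
    SuitabilityMap,
    cells_of,
)
from .pseudoabsence import CaseWeights, PseudoAbsenceSet

logger = logging.getLogger(__name__)

ALGORITHM_FAMILIES = {
    "GLM": "regression",
    "GAM": "regression",
    "BRT": "machine_learning",
    "RF": "machine_learning",
}


def tss(a: float, b: float, c: float, d: float) -> float:
    """True skill statistic from confusion counts.

    ``a`` true positives, ``b`` false positives, ``c`` false negatives,
    ``d`` true negatives (counts may be weighted sums). TSS = sensitivity +
    specificity - 1 = a/(a+c) + d/(b+d) - 1, in [-1, 1].
    """
    if min(a, b, c, d) < 0:
        raise DomainError("confusion counts must be non-negative")
    if a + c <= 0 or b + d <= 0:
        raise DomainError("TSS undefined: one confusion margin is empty")
    return a / (a + c) + d / (b + d) - 1.0


def maxtss_threshold(
    probs: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[float, float]:
    """Probability cutoff maximising (weighted) TSS.

    Candidates are the sorted unique predicted probabilities; prediction is
    ``prob >= threshold``. Returns ``(threshold, tss)`` with the smallest
    candidate achieving the maximum.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    w = np.ones_like(probs) if weights is None else np.asarray(weights, dtype=float)
    if probs.shape != labels.shape or probs.shape != w.shape:
        raise DomainError("probs, labels and weights must have equal length")
    w1 = float((w * labels).sum())
    w0 = float((w * (1.0 - labels)).sum())
    if w1 <= 0 or w0 <= 0:
        raise DomainError("both classes must be present with positive weight")
    order = np.argsort(probs, kind="stable")
    ps = probs[order]
    cw1 = np.concatenate([[0.0], np.cumsum((w * labels)[order])])
    cw0 = np.concatenate([[0.0], np.cumsum((w * (1.0 - labels))[order])])
    cand = np.unique(ps)
    below = np.searchsorted(ps, cand, side="left")  # rows predicted negative
    sens = (w1 - cw1[below]) / w1
    spec = cw0[below] / w0
    scores = sens + spec - 1.0
    best = int(np.argmax(scores))  # first occurrence -> smallest threshold
    return float(cand[best]), float(scores[best])


@dataclass
class TrainingSet:
    """Presence/pseudo-absence rows with climate predictors and case weights."""

    X: pd.DataFrame
    y: np.ndarray
    w: np.ndarray
    species_id: str = ""

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y) or len(self.y) != len(self.w):
            raise DomainError("X, y and w must have equal length")
        if len(np.unique(self.y)) < 2:
            raise DomainError(
                f"training set for {self.species_id!r} has a single class"
            )

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    @classmethod
    def from_points(
        cls,
        stack: ClimateStack,
        presences: pd.DataFrame,
        pa: PseudoAbsenceSet,
        weights: CaseWeights,
        species_id: str = "",
    ) -> "TrainingSet":
        """Extract predictors at presence and pseudo-absence cells.

        Rows whose cell carries missing climate (water) are dropped and
        logged; by construction of both samplers there should be none.
        """
        pts = pd.concat(
            [
                presences[["lon", "lat"]].assign(_y=1.0, _w=weights.w_presence),
                pa.points[["lon", "lat"]].assign(_y=0.0, _w=weights.w_absence),
            ],
            ignore_index=True,
        )
        rows, cols = cells_of(pts["lon"].to_numpy(), pts["lat"].to_numpy(), stack)
        X = pd.DataFrame(
            {name: stack.layers[name][rows, cols] for name in stack.layers}
        )
        ok = ~X.isna().any(axis=1).to_numpy()
        if not ok.all():
            logger.info(
                "species %s: dropped %d training rows with missing climate",
                species_id,
                int((~ok).sum()),
            )
        return cls(
            X=X[ok].reset_index(drop=True),
            y=pts["_y"].to_numpy()[ok],
            w=pts["_w"].to_numpy()[ok],
            species_id=species_id,
        )


# -- algorithms -----------------------------------------------------------


class _SklearnPredictor:
    def __init__(self, est, columns: list[str]):
        self._est = est
        self._columns = columns

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        p = self._est.predict_proba(X[self._columns].to_numpy())
        pos = list(self._est.classes_).index(1.0)
        return p[:, pos]


class _GamPredictor:
    """Fitted spline GAM; new data is clamped to the training range because
    the B-spline basis is undefined beyond the outermost knots."""

    def __init__(self, res, columns: list[str], lo: np.ndarray, hi: np.ndarray):
        self._res = res
        self._columns = columns
        self._lo = lo
        self._hi = hi

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Xa = np.clip(X[self._columns].to_numpy(), self._lo, self._hi)
        with np.errstate(over="ignore"):
            p = self._res.predict(exog=np.ones((len(Xa), 1)), exog_smooth=Xa)
        return np.clip(np.asarray(p), 0.0, 1.0)


def _fit_glm(train: TrainingSet, seed: int):
    # quasi-unpenalised logistic regression with linear + quadratic terms
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("poly", PolynomialFeatures(degree=2, include_bias=False)),
            ("logit", LogisticRegression(C=1e6, max_iter=2000)),
        ]
    )
    pipe.fit(train.X.to_numpy(), train.y, logit__sample_weight=train.w)
    return _SklearnPredictor(pipe, train.columns)


def _fit_gam(train: TrainingSet, seed: int):
    Xa = train.X.to_numpy()
    k = Xa.shape[1]
    smoother = BSplines(Xa, df=[6] * k, degree=[3] * k)
    model = GLMGam(
        train.y,
        exog=np.ones((len(Xa), 1)),
        smoother=smoother,
        family=sm.families.Binomial(),
        var_weights=train.w,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # near-separable presence/background data leaves the likelihood flat;
        # predictions are stable well before full IRLS convergence
        res = model.fit(maxiter=25)
    return _GamPredictor(res, train.columns, Xa.min(axis=0), Xa.max(axis=0))


def _fit_brt(train: TrainingSet, seed: int):
    est = GradientBoostingClassifier(random_state=seed)
    est.fit(train.X.to_numpy(), train.y, sample_weight=train.w)
    return _SklearnPredictor(est, train.columns)


def _fit_rf(train: TrainingSet, seed: int):
    est = RandomForestClassifier(random_state=seed, n_jobs=1)
    est.fit(train.X.to_numpy(), train.y, sample_weight=train.w)
    return _SklearnPredictor(est, train.columns)


_FITTERS = {"GLM": _fit_glm, "GAM": _fit_gam, "BRT": _fit_brt, "RF": _fit_rf}


def _fit_one(train: TrainingSet, algorithm: str, seed: int):
    if algorithm not in _FITTERS:
        raise DomainError(f"unknown algorithm {algorithm!r}")
    try:
        return _FITTERS[algorithm](train, seed)
    except Exception as exc:  # noqa: BLE001 - annotate with context
        raise RuntimeError(
            f"{algorithm} failed to converge for species "
            f"{train.species_id!r}: {exc}"
        ) from exc


@dataclass
class FitResult:
    """One calibrated model with its split-sample evaluation scores."""

    algorithm: str
    species_id: str
    replicate_id: int
    model: object
    train: TrainingSet
    eval_tss: list[float]

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHM_FAMILIES:
            raise DomainError(f"unknown algorithm {self.algorithm!r}")

    @property
    def family(self) -> str:
        return ALGORITHM_FAMILIES[self.algorithm]

    @property
    def mean_tss(self) -> float:
        return float(np.mean(self.eval_tss))


def split_sample_eval(
    train: TrainingSet,
    algorithm: str,
    reps: int = 3,
    calib_frac: float = 0.8,
    seed: int = 0,
) -> list[float]:
    """Repeated stratified split-sample TSS.

    Per repetition: an 80/20 stratified split, a fit on the calibration
    part, prediction of the held-out part, binarisation at the maxTSS
    threshold of the held-out predictions, and the TSS at that threshold.
    """
    rng = np.random.default_rng(seed)
    idx1 = np.nonzero(train.y == 1)[0]
    idx0 = np.nonzero(train.y == 0)[0]
    scores: list[float] = []
    for _ in range(reps):
        for attempt in range(11):
            p1 = rng.permutation(idx1)
            p0 = rng.permutation(idx0)
            n1 = int(round(calib_frac * len(p1)))
            n0 = int(round(calib_frac * len(p0)))
            calib = np.concatenate([p1[:n1], p0[:n0]])
            heldout = np.concatenate([p1[n1:], p0[n0:]])
            ok = (
                len(np.unique(train.y[calib])) == 2
                and len(np.unique(train.y[heldout])) == 2
            )
            if ok:
                break
            logger.info("degenerate split for %s; resplitting", train.species_id)
        else:
            raise DomainError(
                f"could not produce a two-class split for {train.species_id!r}"
            )
        sub = TrainingSet(
            X=train.X.iloc[calib].reset_index(drop=True),
            y=train.y[calib],
            w=train.w[calib],
            species_id=train.species_id,
        )
        model = _fit_one(sub, algorithm, seed=int(rng.integers(2**31 - 1)))
        probs = model.predict(train.X.iloc[heldout])
        _, score = maxtss_threshold(probs, train.y[heldout], train.w[heldout])
        scores.append(score)
    return scores


def fit_full(
    train: TrainingSet,
    algorithm: str,
    eval_tss: list[float],
    seed: int = 0,
    replicate_id: int = 0,
) -> FitResult:
    """Refit on all rows with case weights; attach the evaluation scores."""
    model = _fit_one(train, algorithm, seed)
    return FitResult(
        algorithm=algorithm,
        species_id=train.species_id,
        replicate_id=replicate_id,
        model=model,
        train=train,
        eval_tss=list(eval_tss),
    )


def project(fit: FitResult, stack: ClimateStack) -> SuitabilityMap:
    """Predict per-cell suitability over the stack's land cells."""
    missing = set(fit.train.columns) - set(stack.layers)
    if missing:
        raise DomainError(f"stack lacks training variables {sorted(missing)}")
    frame = stack.land_frame()
    probs = np.clip(fit.model.predict(frame), 0.0, 1.0)
    grid = np.full(stack.shape, np.nan)
    rows, cols = np.nonzero(stack.land_mask)
    grid[rows, cols] = probs
    return SuitabilityMap(grid, species_id=fit.species_id, scenario_id=stack.scenario_id)


def ensemble_weighted_mean(
    maps: list[SuitabilityMap], scores: list[float]
) -> SuitabilityMap:
    """TSS-weighted mean of member suitability maps.

    Members with non-positive scores are dropped with a warning; if none
    remain the ensemble is undefined.
    """
    if len(maps) != len(scores) or not maps:
        raise DomainError("need one score per map and at least one map")
    keep = [i for i, s in enumerate(scores) if s > 0]
    if len(keep) < len(maps):
        warnings.warn(
            f"dropping {len(maps) - len(keep)} ensemble member(s) with "
            "non-positive TSS",
            stacklevel=2,
        )
    if not keep:
        raise DomainError("all ensemble weights are non-positive")
    arr = np.stack([maps[i].values for i in keep])
    w = np.asarray([scores[i] for i in keep], dtype=float)
    mean = np.tensordot(w, arr, axes=1) / w.sum()
    return SuitabilityMap(
        mean, species_id=maps[keep[0]].species_id, scenario_id=maps[keep[0]].scenario_id
    )


@dataclass
class EnsembleResult:
    """One family's weighted-mean projection with its maxTSS binary."""

    family: str
    suitability: SuitabilityMap
    threshold: float
    binary: BinaryMap
    member_algorithms: list[str] = field(default_factory=list)
    member_weights: list[float] = field(default_factory=list)


def _family_members(fits: list[FitResult], family: str) -> list[FitResult]:
    members = [f for f in fits if f.family == family]
    if not members:
        raise DomainError(f"no fitted members for family {family!r}")
    kept = [f for f in members if f.mean_tss > 0]
    if len(kept) < len(members):
        warnings.warn(
            f"family {family}: dropping {len(members) - len(kept)} member(s) "
            "with non-positive mean TSS",
            stacklevel=3,
        )
    if not kept:
        raise DomainError(f"family {family!r} has no member with positive TSS")
    return kept


def family_threshold(fits: list[FitResult], family: str) -> float:
    """maxTSS cutoff for a family ensemble, from pooled calibration data.

    All member training rows are pooled (with their case weights), scored
    by the TSS-weighted mean of the member models, and scanned for the
    TSS-maximising cutoff. Scenario-independent, so computed once per
    species and family.
    """
    members = _family_members(fits, family)
    X = pd.concat([f.train.X for f in members], ignore_index=True)
    y = np.concatenate([f.train.y for f in members])
    w = np.concatenate([f.train.w for f in members])
    wts = np.asarray([f.mean_tss for f in members])
    probs = np.zeros(len(X))
    for f, wt in zip(members, wts):
        probs += wt * f.model.predict(X)
    probs /= wts.sum()
    thr, _ = maxtss_threshold(probs, y, w)
    return thr


def build_family_ensembles(
    fits: list[FitResult],
    stack: ClimateStack,
    thresholds: dict[str, float] | None = None,
) -> dict[str, EnsembleResult]:
    """Project and combine each family's members into its ensemble.

    Returns one :class:`EnsembleResult` per family present among ``fits``
    (under the default design: regression with 2 members, machine learning
    with 2 algorithms x 10 pseudo-absence replicates = 20 members).
    """
    out: dict[str, EnsembleResult] = {}
    for family in sorted({f.family for f in fits}):
        members = _family_members(fits, family)
        maps = [project(f, stack) for f in members]
        scores = [f.mean_tss for f in members]
        mean_map = ensemble_weighted_mean(maps, scores)
        thr = (
            thresholds[family]
            if thresholds is not None
            else family_threshold(fits, family)
        )
        if not (0.0 < thr < 1.0):
            logger.info("family %s: threshold %.3f at the probability edge", family, thr)
        binary = np.where(
            np.isnan(mean_map.values), np.nan, (mean_map.values >= thr).astype(float)
        )
        out[family] = EnsembleResult(
            family=family,
            suitability=mean_map,
            threshold=float(thr),
            binary=BinaryMap(
                binary,
                species_id=mean_map.species_id,
                scenario_id=mean_map.scenario_id,
            ),
            member_algorithms=[f.algorithm for f in members],
            member_weights=scores,
        )
    return out


def consensus_binary(reg: BinaryMap, ml: BinaryMap) -> BinaryMap:
    """Conservative consensus: suitable only where both families agree."""
    if reg.values.shape != ml.values.shape:
        raise DomainError("family binaries live on different grids")
    a = reg.values
    b = ml.values
    if not np.array_equal(np.isnan(a), np.isnan(b)):
        raise DomainError("family binaries have different no-data masks")
    both = np.where(np.isnan(a), np.nan, ((a > 0) & (b > 0)).astype(float))
    return BinaryMap(both, species_id=reg.species_id, scenario_id=reg.scenario_id)
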