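"""Selective subject pooling and transfer evaluation.

The core idea: a subject enters the source pool for subject-independent
(SI) training only if their subject-specific (SS) decoding accuracy exceeds
the upper confidence limit of the chance level,

    p0 ± z_{1-alpha/2} * sqrt(p0 (1 - p0) / (n + 4)),

an adjusted binomial interval in the number of test trials n.  For balanced
binary motor imagery p0 = 0.5 and the upper limit serves as the pooling
threshold at significance alpha.

Evaluation protocols:

* SS        — train and test on the same subject;
* SI-All    — leave-one-subject-out over every available subject;
* SI-alpha  — leave-one-subject-out over the selective pool only;
* CROSS     — train a single model on one dataset's (pooled) subjects and
              test per subject of another dataset on a harmonized montage.

Every leave-one-subject-out fold records the ids it trained on so exclusion
of the evaluated subject is auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .classification import LDAModel, accuracy, fit_slda, predict
from .io_types import Epochs, MultiSubjectDataset, concatenate_epochs
from .preprocessing import BandSpec, bandpass, crop
from .spatial_filters import (
    FBCSPModel,
    SpatialFilterSet,
    class_scatter,
    csp_features,
    csp_from_covariances,
    fit_csp,
    fit_fbcsp,
    select_filters,
)

__all__ = [
    "ChanceLevelSpec",
    "chance_limits",
    "threshold_table",
    "PipelineConfig",
    "DecodingPipeline",
    "SubjectRecord",
    "SubjectPool",
    "EvalTable",
    "subject_specific_eval",
    "ss_records",
    "build_pool",
    "pooled_train",
    "losocv",
    "cross_dataset_eval",
    "subsample_trials",
    "subsample_dataset",
    "wilcoxon_compare",
]


# --- chance-level confidence limits --------------------------------------------

@dataclass(frozen=True)
class ChanceLevelSpec:
    """Expected chance level p0, number of test trials n, significance alpha."""

    p0: float = 0.5
    n: int = 100
    alpha: float = 0.05

    def __post_init__(self):
        if not 0 < self.p0 < 1:
            raise ValueError(f"p0 must lie in (0, 1), got {self.p0}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")


def chance_limits(spec: ChanceLevelSpec) -> tuple[float, float]:
    """Lower and upper chance-level confidence limits.

    Adjusted interval ``p0 ± z_{1-alpha/2} sqrt(p0(1-p0)/(n+4))`` — the "+4"
    keeps the interval honest at small n.  The upper limit is the pooling
    threshold: accuracy above it is significantly better than guessing.
    """
    z = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    half = z * np.sqrt(spec.p0 * (1.0 - spec.p0) / (spec.n + 4))
    return float(spec.p0 - half), float(spec.p0 + half)


def threshold_table(
    ns: tuple[int, ...] = (50, 100, 150, 200),
    alphas: tuple[float, ...] = (0.05, 0.01, 0.005, 0.001),
    p0: float = 0.5,
) -> pd.DataFrame:
    """Pooling thresholds (upper limits) for a grid of trial counts and alphas."""
    rows = {
        n: {a: chance_limits(ChanceLevelSpec(p0, n, a))[1] for a in alphas} for n in ns
    }
    tab = pd.DataFrame.from_dict(rows, orient="index")
    tab.index.name = "trials"
    tab.columns.name = "alpha"
    return tab


# --- decoding pipeline ---------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Feature/classifier configuration shared by all protocols.

    ``feature``: "csp" (single 8-30 Hz band) or "fbcsp" (15-band bank).
    ``m_pairs_ss`` / ``m_pairs_si``: CSP filter pairs for subject-specific
    vs subject-independent training (2 and 3 respectively by default).
    ``k_pairs``: feature pairs kept by MIBIF selection in filter-bank mode.
    """

    feature: str = "csp"
    m_pairs_ss: int = 2
    m_pairs_si: int = 3
    k_pairs: int = 10
    band: tuple[float, float] = (8.0, 30.0)
    window: tuple[float, float] = (1.0, 3.5)
    fb_m_pairs: int = 2
    lda_gamma: float | str = "auto"

    def __post_init__(self):
        if self.feature not in ("csp", "fbcsp"):
            raise ValueError(f"unknown feature method {self.feature!r}")

    def snapshot(self) -> dict:
        return {
            "feature": self.feature,
            "m_pairs_ss": self.m_pairs_ss,
            "m_pairs_si": self.m_pairs_si,
            "k_pairs": self.k_pairs,
            "band": list(self.band),
            "window": list(self.window),
            "fb_m_pairs": self.fb_m_pairs,
            "lda_gamma": self.lda_gamma,
        }


class DecodingPipeline:
    """Band-pass -> crop -> spatial filtering -> log-variance -> shrinkage LDA.

    ``m_pairs`` selects the CSP filter-pair count (single-band mode only);
    filter-bank mode always keeps ``config.fb_m_pairs`` pairs per band before
    MIBIF selection.

    ``preprocessed=True`` declares that incoming epochs are already
    band-passed and cropped (single-band mode only); the evaluation drivers
    use this to filter each subject once instead of once per fold.
    """

    def __init__(self, config: PipelineConfig, m_pairs: int, preprocessed: bool = False):
        if preprocessed and config.feature != "csp":
            raise ValueError("preprocessed epochs are only supported in single-band mode")
        self.config = config
        self.m_pairs = m_pairs
        self.preprocessed = preprocessed
        self.spatial_: SpatialFilterSet | FBCSPModel | None = None
        self.lda_: LDAModel | None = None

    def _prep(self, e: Epochs) -> Epochs:
        if self.preprocessed:
            return e
        return crop(bandpass(e, BandSpec(*self.config.band)), *self.config.window)

    def _features(self, e: Epochs) -> np.ndarray:
        if self.config.feature == "csp":
            return csp_features(self.spatial_, self._prep(e))
        return self.spatial_.transform(e)

    def fit(self, train: Epochs) -> "DecodingPipeline":
        cfg = self.config
        if cfg.feature == "csp":
            eb = self._prep(train)
            self.spatial_ = select_filters(fit_csp(eb), self.m_pairs)
            X = csp_features(self.spatial_, eb)
        else:
            self.spatial_ = fit_fbcsp(
                train, cfg.k_pairs, window=cfg.window, m=cfg.fb_m_pairs
            )
            X = self.spatial_.transform(train)
        self.lda_ = fit_slda(X, train.labels, gamma=cfg.lda_gamma)
        return self

    def predict(self, e: Epochs) -> np.ndarray:
        if self.lda_ is None:
            raise RuntimeError("pipeline is not fitted")
        return predict(self.lda_, self._features(e))

    def score(self, e: Epochs) -> float:
        return accuracy(self.predict(e), e.labels)


# --- subject records and the selective pool ------------------------------------

@dataclass(frozen=True)
class SubjectRecord:
    """One subject's subject-specific accuracy on n test trials."""

    subject_id: str
    ss_accuracy: float
    n_test_trials: int

    def __post_init__(self):
        if not 0.0 <= self.ss_accuracy <= 1.0:
            raise ValueError(f"accuracy {self.ss_accuracy} outside [0, 1]")


@dataclass(frozen=True)
class SubjectPool:
    """Subjects whose SS accuracy strictly exceeds the chance threshold."""

    member_ids: tuple[str, ...]
    threshold: float
    alpha: float
    n: int


def _prep_dataset(d: MultiSubjectDataset, config: PipelineConfig) -> MultiSubjectDataset:
    """Band-pass and crop every split once (single-band mode).

    The evaluation drivers call this so each subject is filtered a single
    time rather than once per cross-validation fold; results are identical
    because filtering and cropping are per-trial operations.
    """
    band = BandSpec(*config.band)
    subjects = {
        sid: {split: crop(bandpass(e, band), *config.window) for split, e in splits.items()}
        for sid, splits in d.subjects.items()
    }
    return MultiSubjectDataset(subjects=subjects, name=d.name, montage=list(d.montage),
                               meta=d.meta)


def subject_specific_eval(
    d: MultiSubjectDataset, subject_id: str, config: PipelineConfig
) -> SubjectRecord:
    """Train on the subject's train split, score on their test split."""
    splits = d.subjects[subject_id]
    pipe = DecodingPipeline(config, m_pairs=config.m_pairs_ss).fit(splits["train"])
    acc = pipe.score(splits["test"])
    return SubjectRecord(subject_id, acc, splits["test"].n_trials)


def ss_records(d: MultiSubjectDataset, config: PipelineConfig) -> list[SubjectRecord]:
    """Subject-specific records for every subject, in id order."""
    if config.feature != "csp":
        return [subject_specific_eval(d, sid, config) for sid in d.subject_ids]
    prepped = _prep_dataset(d, config)
    out = []
    for sid in prepped.subject_ids:
        splits = prepped.subjects[sid]
        pipe = DecodingPipeline(config, config.m_pairs_ss, preprocessed=True)
        acc = pipe.fit(splits["train"]).score(splits["test"])
        out.append(SubjectRecord(sid, acc, splits["test"].n_trials))
    return out


def build_pool(records: list[SubjectRecord], alpha: float) -> SubjectPool:
    """Threshold SS records at the upper chance limit for their trial count.

    Membership uses a strict ``>`` comparison; accuracies exactly on the
    threshold are excluded.  All records must share ``n_test_trials`` (the
    threshold is a function of n).
    """
    if not records:
        raise ValueError("no subject records")
    ns = {r.n_test_trials for r in records}
    if len(ns) != 1:
        raise ValueError(f"heterogeneous test-trial counts {sorted(ns)}: threshold ill-defined")
    n = ns.pop()
    _, upper = chance_limits(ChanceLevelSpec(0.5, n, alpha))
    members = tuple(sorted(r.subject_id for r in records if r.ss_accuracy > upper))
    return SubjectPool(member_ids=members, threshold=upper, alpha=alpha, n=n)


def pooled_train(
    d: MultiSubjectDataset,
    pool: SubjectPool | tuple[str, ...],
    exclude: str | None,
    config: PipelineConfig,
    preprocessed: bool = False,
) -> tuple[DecodingPipeline, tuple[str, ...]]:
    """Fit one pipeline on the concatenated train splits of the pool.

    The evaluated subject (``exclude``) is removed from the pool if present.
    Returns the fitted pipeline and the tuple of subject ids actually used
    (the training manifest for the exclusion audit).  ``preprocessed``
    declares that ``d`` already went through :func:`_prep_dataset`.
    """
    ids = pool.member_ids if isinstance(pool, SubjectPool) else tuple(pool)
    source_ids = tuple(sid for sid in sorted(ids) if sid != exclude)
    if not source_ids:
        raise ValueError(f"no source subjects left after excluding {exclude!r}")
    train = concatenate_epochs([d.subjects[sid]["train"] for sid in source_ids])
    pipe = DecodingPipeline(config, m_pairs=config.m_pairs_si,
                            preprocessed=preprocessed).fit(train)
    return pipe, source_ids


# --- evaluation tables ---------------------------------------------------------

@dataclass
class EvalTable:
    """Per-subject accuracies under a named strategy, plus provenance."""

    strategy: str
    per_subject: dict[str, float]
    config: dict
    audit: dict[str, tuple[str, ...]] = field(default_factory=dict)
    missing: list[str] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.per_subject.values())))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": list(self.per_subject),
                "strategy": self.strategy,
                "accuracy": list(self.per_subject.values()),
            }
        )


def losocv(
    d: MultiSubjectDataset,
    config: PipelineConfig,
    strategy: str | float = "all",
    records: list[SubjectRecord] | None = None,
) -> EvalTable:
    """Leave-one-subject-out evaluation, with or without selective pooling.

    ``strategy="all"`` trains each fold on every other subject (SI-All).  A
    float ``alpha`` builds the selective pool once from subject-specific
    CSP-LDA records (computed here unless ``records`` is supplied) and each
    fold trains on the pool minus the evaluated subject (SI-alpha).  Folds
    whose effective pool is empty are reported under ``missing`` and excluded
    from the mean, with a warning.
    """
    sids = d.subject_ids
    if len(sids) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    if strategy == "all":
        pool_ids: tuple[str, ...] = tuple(sids)
        name = "SI-All"
        pool_info: dict = {"pool": "all"}
    else:
        alpha = float(strategy)
        if records is None:
            # the pool criterion is always single-band CSP + shrinkage LDA,
            # regardless of the feature method being evaluated
            records = ss_records(d, replace(config, feature="csp"))
        pool = build_pool(records, alpha)
        pool_ids = pool.member_ids
        name = f"SI-alpha={alpha:g}"
        pool_info = {"pool": list(pool_ids), "threshold": pool.threshold, "alpha": alpha}
    per_subject: dict[str, float]
    audit: dict[str, tuple[str, ...]]
    missing: list[str]
    if config.feature == "csp":
        per_subject, audit, missing = _losocv_csp_folds(d, config, pool_ids)
    else:
        per_subject, audit, missing = {}, {}, []
        for sid in sids:
            try:
                pipe, used = pooled_train(d, pool_ids, exclude=sid, config=config)
            except ValueError:
                missing.append(sid)
                continue
            assert sid not in used  # exclusion audit, re-checked by callers
            audit[sid] = used
            per_subject[sid] = pipe.score(d.subjects[sid]["test"])
    if missing:
        warnings.warn(f"empty effective pool for subjects {missing}; excluded from mean")
    if not per_subject:
        raise ValueError("every fold had an empty effective pool")
    snap = dict(config.snapshot(), **pool_info)
    return EvalTable(strategy=name, per_subject=per_subject, config=snap,
                     audit=audit, missing=missing)


def _losocv_csp_folds(
    d: MultiSubjectDataset, config: PipelineConfig, pool_ids: tuple[str, ...]
) -> tuple[dict[str, float], dict[str, tuple[str, ...]], list[str]]:
    """Single-band fold loop, algebraically identical to pooled_train per fold.

    Each subject is band-passed and cropped once; per-class scatter matrices
    are additive across subjects, so each fold's pooled covariances are
    assembled by summation instead of re-concatenating and re-filtering the
    raw data.  Features and the LDA fit are computed per fold as usual.
    """
    prepped = _prep_dataset(d, config)
    first = next(iter(prepped.subjects.values()))["train"]
    c1, c2 = (int(c) for c in first.class_ids)
    scat = {
        sid: {c: class_scatter(splits["train"], c) for c in (c1, c2)}
        for sid, splits in prepped.subjects.items()
    }
    per_subject: dict[str, float] = {}
    audit: dict[str, tuple[str, ...]] = {}
    missing: list[str] = []
    for sid in prepped.subject_ids:
        source_ids = tuple(s for s in sorted(pool_ids) if s != sid)
        if not source_ids:
            missing.append(sid)
            continue
        assert sid not in source_ids
        covs = {}
        for c in (c1, c2):
            total = sum(scat[s][c][0] for s in source_ids)
            n = sum(scat[s][c][1] for s in source_ids)
            covs[c] = total / n
        model = csp_from_covariances(covs[c1], covs[c2], class_order=(c1, c2),
                                     channels=list(prepped.montage))
        fset = select_filters(model, config.m_pairs_si)
        X = np.vstack([csp_features(fset, prepped.subjects[s]["train"]) for s in source_ids])
        y = np.concatenate([prepped.subjects[s]["train"].labels for s in source_ids])
        lda = fit_slda(X, y, gamma=config.lda_gamma)
        test = prepped.subjects[sid]["test"]
        per_subject[sid] = accuracy(predict(lda, csp_features(fset, test)), test.labels)
        audit[sid] = source_ids
    return per_subject, audit, missing


def cross_dataset_eval(
    train_d: MultiSubjectDataset,
    test_d: MultiSubjectDataset,
    config: PipelineConfig,
    strategy: str | float = "all",
    records: list[SubjectRecord] | None = None,
) -> EvalTable:
    """Train one model on (a pool of) ``train_d`` and test per ``test_d`` subject.

    Both datasets must already be harmonized to the same montage (same names
    in the same order); a mismatch raises before any training.  No exclusion
    is needed since the test subjects are disjoint from the training dataset.
    """
    if train_d.montage != test_d.montage:
        diff = sorted(set(train_d.montage) ^ set(test_d.montage)) or ["(ordering differs)"]
        raise ValueError(f"montage mismatch between datasets: {diff}")
    if strategy == "all":
        pool_ids: tuple[str, ...] = tuple(train_d.subject_ids)
        name = "CROSS-All"
        pool_info: dict = {"pool": "all"}
    else:
        alpha = float(strategy)
        if records is None:
            records = ss_records(train_d, replace(config, feature="csp"))
        pool = build_pool(records, alpha)
        pool_ids = pool.member_ids
        name = f"CROSS-alpha={alpha:g}"
        pool_info = {"pool": list(pool_ids), "threshold": pool.threshold, "alpha": alpha}
    pipe, used = pooled_train(train_d, pool_ids, exclude=None, config=config)
    per_subject = {sid: pipe.score(test_d.subjects[sid]["test"]) for sid in test_d.subject_ids}
    snap = dict(config.snapshot(), **pool_info,
                train_dataset=train_d.name, test_dataset=test_d.name)
    return EvalTable(strategy=name, per_subject=per_subject, config=snap,
                     audit={sid: used for sid in per_subject})


# --- sub-trial subsampling -----------------------------------------------------

def subsample_trials(e: Epochs, n_sub: int, seed: int) -> Epochs:
    """Draw ``n_sub/2`` trials per class without replacement, preserving order."""
    if n_sub % 2 != 0:
        raise ValueError(f"n_sub must be even (balanced classes), got {n_sub}")
    if n_sub > e.n_trials:
        raise ValueError(f"n_sub={n_sub} exceeds available {e.n_trials} trials")
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for c in e.class_ids:
        idx = np.flatnonzero(e.labels == c)
        if idx.size < n_sub // 2:
            raise ValueError(f"class {c} has only {idx.size} trials, need {n_sub // 2}")
        keep.append(rng.choice(idx, size=n_sub // 2, replace=False))
    order = np.sort(np.concatenate(keep))
    return Epochs(e.data[:, :, order].copy(), e.labels[order].copy(),
                  e.fs, list(e.channels), e.t0)


def subsample_dataset(d: MultiSubjectDataset, n_sub: int, seed: int) -> MultiSubjectDataset:
    """Subsample every subject's train and test split to ``n_sub`` trials.

    Per-split seeds are derived deterministically from ``seed`` and the
    subject index so subsets do not depend on iteration order.
    """
    subjects = {}
    for i, sid in enumerate(d.subject_ids):
        subjects[sid] = {
            split: subsample_trials(
                d.subjects[sid][split], n_sub,
                int(np.random.SeedSequence([seed, i, j]).generate_state(1)[0] % 2**31),
            )
            for j, split in enumerate(("train", "test"))
        }
    return MultiSubjectDataset(subjects=subjects, name=f"{d.name}_sub{n_sub}",
                               montage=list(d.montage), meta=dict(d.meta))


# --- paired comparison ---------------------------------------------------------

def wilcoxon_compare(a, b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired per-subject accuracies.

    Zero differences are dropped (Wilcoxon convention); if every difference
    is zero the comparison is degenerate and p = 1 is returned with a
    warning.  Exact null distribution for n <= 25 pairs without ties, normal
    approximation otherwise (scipy's automatic policy).
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 5:
        raise ValueError(f"need at least 5 pairs, got {a.size}")
    if np.all(a == b):
        warnings.warn("all paired differences are zero; p-value degenerate at 1.0")
        return 1.0
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return float(res.pvalue)
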