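"""Common spatial patterns (CSP) and the multi-resolution filter-bank
variant with mutual-information feature selection.

CSP solves the generalized eigenproblem

    W' S1 W = D,    W' S2 W = I - D

where S1, S2 are the trial-concatenated class covariances.  Columns of W are
spatial filters ordered by descending relative class-1 variance d; the first
filters maximize band power for class 1 (left hand), the last for class 2.
Log-variance of the projected, sum-normalized signal is the feature.

The filter-bank variant fits one CSP per band of the 15-band filter bank,
keeps two filter pairs per band (60 features) and prunes to the best k
feature pairs by mutual information with the class label (MIBIF selection
with pair closure: a selected feature always brings along the filter from
the opposite end of the same band's spectrum).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .io_types import Epochs
from .preprocessing import BandSpec, bandpass, crop, make_filter_bank

__all__ = [
    "CSPModel",
    "SpatialFilterSet",
    "FBCSPModel",
    "class_covariance",
    "class_scatter",
    "fit_csp",
    "csp_from_covariances",
    "select_filters",
    "csp_features",
    "mutual_information",
    "mibifs_select",
    "fit_fbcsp",
    "pattern_table",
]


# --- covariance and the CSP eigenproblem ---------------------------------------

def class_scatter(e: Epochs, label: int) -> tuple[np.ndarray, int]:
    """Unnormalized scatter matrix and sample count for one class.

    Each trial is mean-centered per channel; the scatter is the sum of outer
    products over all time points of all trials of the class.  Scatters are
    additive across subjects, which lets pooled covariances be assembled
    without concatenating raw data.
    """
    mask = e.labels == label
    if not mask.any():
        raise ValueError(f"no trials with label {label}")
    X = e.data[:, :, mask]  # (T, C, n)
    X = X - X.mean(axis=0, keepdims=True)
    scatter = np.einsum("tcn,tdn->cd", X, X)
    return scatter, X.shape[0] * X.shape[2]


def class_covariance(e: Epochs, label: int) -> np.ndarray:
    """Trial-concatenated sample covariance [C × C] of one class.

    Each trial is mean-centered per channel, all trials of the class are
    concatenated along time, and the (population) covariance of the resulting
    C × T_total signal is returned.  The 1/T_total normalization makes the
    estimate exactly invariant to duplicating trials.
    """
    scatter, n = class_scatter(e, label)
    return scatter / n


@dataclass
class CSPModel:
    """Full CSP decomposition for one binary problem.

    ``W`` holds all C spatial filters as columns; ``d`` the relative class-1
    variances (descending, in [0, 1]); ``patterns`` the inverse-transpose of
    ``W`` for topographic inspection; ``class_order`` records which label is
    treated as class 1 / class 2.
    """

    W: np.ndarray
    d: np.ndarray
    patterns: np.ndarray
    class_order: tuple[int, int]
    channels: list[str] = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]


def fit_csp(e: Epochs, ridge: float | None = None) -> CSPModel:
    """Fit CSP from the two class covariances of ``e``.

    Solves ``S1 w = lam (S1 + S2) w``; eigenvalues are the relative
    class-1 variances d, sorted descending, and the whitening constraint
    ``W'(S1+S2)W = I`` is inherited from the symmetric eigensolver.  Ties in
    d are broken by ascending original eigenvector index.  Each filter is
    scaled so its largest-magnitude entry is positive (sign convention only;
    variances are sign-invariant).

    ``ridge`` optionally adds ``ridge * trace/C * I`` to the composite
    covariance; by default a rank-deficient composite raises instead.
    """
    c1, c2 = (int(c) for c in e.class_ids)
    s1 = class_covariance(e, c1)
    s2 = class_covariance(e, c2)
    return csp_from_covariances(s1, s2, class_order=(c1, c2),
                                channels=list(e.channels), ridge=ridge)


def csp_from_covariances(
    s1: np.ndarray,
    s2: np.ndarray,
    class_order: tuple[int, int] = (1, 2),
    channels: list[str] | None = None,
    ridge: float | None = None,
) -> CSPModel:
    """Fit CSP directly from precomputed class covariances (see fit_csp)."""
    comp = s1 + s2
    C = comp.shape[0]
    if ridge is not None:
        comp = comp + ridge * np.trace(comp) / C * np.eye(C)
    evals = linalg.eigvalsh(comp)
    if evals[0] <= max(evals[-1], 1.0) * 1e-10:
        raise np.linalg.LinAlgError(
            "composite covariance S1+S2 is rank-deficient; pass ridge=... to "
            "regularize (e.g. ridge=1e-9) or supply more/cleaner trials"
        )
    lam, V = linalg.eigh(s1, comp)  # ascending lam, V'(S1+S2)V = I
    order = np.argsort(-lam, kind="stable")  # descending; ties keep ascending index
    lam, V = lam[order], V[:, order]
    lam = np.clip(lam, 0.0, 1.0)
    # sign convention: largest-|w| entry positive per column
    flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(C)])
    flip[flip == 0] = 1.0
    W = V * flip
    patterns = np.linalg.inv(W).T
    return CSPModel(W=W, d=lam, patterns=patterns, class_order=class_order,
                    channels=list(channels or []))


@dataclass
class SpatialFilterSet:
    """The first m and last m columns of a CSP projection, in that order."""

    filters: np.ndarray  # [C × 2m]
    m: int
    channels: list[str] = field(default_factory=list)


def select_filters(model: CSPModel, m: int) -> SpatialFilterSet:
    """Keep the ``m`` most class-1- and ``m`` most class-2-discriminative filters."""
    C = model.n_channels
    if 2 * m > C:
        raise ValueError(f"2m = {2 * m} filters requested from a {C}-channel model")
    cols = list(range(m)) + list(range(C - m, C))
    return SpatialFilterSet(filters=model.W[:, cols].copy(), m=m,
                            channels=list(model.channels))


def csp_features(fs: SpatialFilterSet, e: Epochs) -> np.ndarray:
    """Log of sum-normalized variance of each spatially filtered trial.

    Returns ``[N × 2m]``.  Per trial the 2m projected variances are divided
    by their sum (making the feature invariant to trial amplitude scaling)
    and log-transformed.
    """
    if e.n_channels != fs.filters.shape[0]:
        raise ValueError(
            f"epochs have {e.n_channels} channels, filters expect {fs.filters.shape[0]}"
        )
    # (T, C, N) -> projected (T, 2m, N)
    proj = np.einsum("tcn,ck->tkn", e.data, fs.filters)
    var = proj.var(axis=0)  # (2m, N)
    total = var.sum(axis=0)
    dead = np.flatnonzero(total <= 0)
    if dead.size:
        raise ValueError(f"zero total projected variance in trial(s) {dead.tolist()}")
    return np.log(var / total).T


# --- mutual information and MIBIF selection ------------------------------------

def _discretize(f: np.ndarray, bins: int | None) -> np.ndarray:
    """Equal-frequency binning; default bin count ceil(sqrt(N)) capped at 16."""
    n = f.size
    if bins is None:
        bins = min(16, math.ceil(math.sqrt(n)))
    edges = np.unique(np.quantile(f, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.searchsorted(edges, f, side="right")


def mutual_information(f: np.ndarray, labels: np.ndarray, bins: int | None = None) -> float:
    """Plug-in estimate of I(feature; class) in bits, >= 0.

    The feature is discretized into equal-frequency bins (``ceil(sqrt(N))``,
    capped at 16, unless ``bins`` is given) and the discrete plug-in mutual
    information is computed from the joint histogram.  A constant feature
    yields exactly 0.
    """
    f = np.asarray(f, dtype=float)
    labels = np.asarray(labels)
    if f.size < 2:
        raise ValueError("need at least 2 samples")
    if len(np.unique(labels)) != 2:
        raise ValueError("need exactly two classes")
    fb = _discretize(f, bins)
    joint = pd.crosstab(fb, labels).to_numpy(dtype=float)
    p = joint / joint.sum()
    pf = p.sum(axis=1, keepdims=True)
    pc = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (pf * pc))
    return float(max(0.0, np.nansum(terms)))


def _complement_index(i: int) -> int:
    """CSP pair complement within a band's block of 4 features.

    Features are laid out per band as [first, second, second-last, last]
    filter variances; the complement mirrors the index within the block, so a
    class-1 filter pairs with the corresponding class-2 filter.
    """
    band, j = divmod(i, 4)
    return band * 4 + (3 - j)


def mibifs_select(
    features: np.ndarray,
    labels: np.ndarray,
    k_pairs: int,
    bins: int | None = None,
) -> np.ndarray:
    """Mutual-information best-individual-feature selection with pair closure.

    Features are ranked by individual MI with the class label (descending,
    ties broken by ascending column index).  Walking down the ranking, each
    feature pulls in its CSP complement — the mirrored filter of the same
    band — and the walk stops once ``k_pairs`` distinct filter pairs are
    selected.  Returns the selected column indices in ascending order.
    """
    features = np.asarray(features, dtype=float)
    n, F = features.shape
    if F % 4 != 0:
        raise ValueError(f"feature count {F} is not 4 per band (2 filter pairs per band)")
    if not 1 <= k_pairs <= F // 2:
        raise ValueError(f"k_pairs={k_pairs} outside [1, {F // 2}]")
    mi = np.array([mutual_information(features[:, j], labels, bins=bins) for j in range(F)])
    order = np.argsort(-mi, kind="stable")
    chosen: set[int] = set()
    pairs_taken = 0
    for idx in order:
        idx = int(idx)
        if idx in chosen:
            continue
        chosen.update((idx, _complement_index(idx)))
        pairs_taken += 1
        if pairs_taken == k_pairs:
            break
    return np.array(sorted(chosen), dtype=int)


# --- filter-bank CSP -----------------------------------------------------------

@dataclass
class FBCSPModel:
    """Per-band CSP filter pairs plus the MIBIF-selected feature subset."""

    bands: list[BandSpec]
    per_band_filters: list[SpatialFilterSet]
    selected: np.ndarray
    k_pairs: int
    window: tuple[float, float] | None = None

    def transform(self, e: Epochs) -> np.ndarray:
        """Features [N × len(selected)] for broadband epochs ``e``."""
        blocks = []
        for band, fset in zip(self.bands, self.per_band_filters):
            eb = bandpass(e, band)
            if self.window is not None:
                eb = crop(eb, *self.window)
            blocks.append(csp_features(fset, eb))
        return np.hstack(blocks)[:, self.selected]


def fit_fbcsp(
    e: Epochs,
    k_pairs: int,
    bands: list[BandSpec] | None = None,
    window: tuple[float, float] | None = None,
    m: int = 2,
    bins: int | None = None,
) -> FBCSPModel:
    """Fit the multi-resolution filter-bank CSP on broadband epochs.

    For each band: band-pass, optionally crop to ``window``, fit CSP, keep
    ``m`` filter pairs, extract log-variance features.  The concatenated
    4-per-band features (60 for the default bank) are pruned to the best
    ``k_pairs`` feature pairs by :func:`mibifs_select`.
    """
    bands = make_filter_bank() if bands is None else list(bands)
    fsets, blocks = [], []
    for band in bands:
        eb = bandpass(e, band)
        if window is not None:
            eb = crop(eb, *window)
        model = fit_csp(eb)
        fset = select_filters(model, m)
        fsets.append(fset)
        blocks.append(csp_features(fset, eb))
    features = np.hstack(blocks)
    selected = mibifs_select(features, e.labels, k_pairs, bins=bins)
    return FBCSPModel(bands=bands, per_band_filters=fsets, selected=selected,
                      k_pairs=k_pairs, window=window)


# --- topographic export --------------------------------------------------------

def pattern_table(model: CSPModel, montage: list[str] | None = None) -> pd.DataFrame:
    """Per-filter channel weights of the activation patterns as a tidy table.

    Rows are channels, columns ``filter_1 .. filter_C`` (pattern columns).
    With ``montage`` given, channels absent from the model are zero-padded so
    the table covers a full scalp layout.
    """
    cols = [f"filter_{j + 1}" for j in range(model.n_channels)]
    tab = pd.DataFrame(model.patterns, index=model.channels, columns=cols)
    if montage is not None:
        tab = tab.reindex(montage, fill_value=0.0)
    tab.index.name = "channel"
    return tab
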