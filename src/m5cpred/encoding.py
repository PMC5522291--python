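"""Pseudo dinucleotide composition via auto/cross-covariance.

A window of length L is read as its L-1 overlapping dinucleotides.  Each of
the 10 standardized physical-chemical properties turns the window into a
numeric profile, and lagged covariances of those profiles form the feature
vector: for each lag g = 1..lam,

    AC(m, g)        = (1/(L-1-g)) * sum_i (P_m(D_i) - mean_m)(P_m(D_{i+g}) - mean_m)
    CC(m1, m2, g)   = (1/(L-1-g)) * sum_i (P_m1(D_i) - mean_m1)(P_m2(D_{i+g}) - mean_m2)

where D_i is the dinucleotide starting at position i and mean_m is the mean
of property m over the window's own L-1 dinucleotides.  The layout is
lag-major: AC(1,1)..AC(10,1), ..., AC(1,lam)..AC(10,lam) fills the first
10*lam components, then the 90 ordered property pairs (m1 != m2, lexicographic)
per lag fill the rest, giving 100*lam components — 500 at the default lam=5.
An optional k-mer composition block can be appended.

``PseDncEncoder`` wraps this as a scikit-learn transformer so the encoding
composes with pipelines and model selection.
"""

from __future__ import annotations

from itertools import permutations, product
from typing import Iterable

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import InputError
from .properties import ALPHABET, DINUC_INDEX, PropertyTable, load_property_table, standardize
from .windows import BenchmarkDataset, POSITIVE

#: identifies the feature layout; stored in model files so a saved model is
#: never applied to features laid out differently
LAYOUT_VERSION = "acc-lagmajor-1"

DEFAULT_LAM = 5


def kmer_composition(window: str, k: int) -> np.ndarray:
    """Normalized k-mer occurrence frequencies, components in alphabetical order.

    Component i is (count of the i-th k-mer) / (L - k + 1); the vector has
    length 4**k and sums to 1.
    """
    if k < 1:
        raise InputError(f"k must be >= 1, got {k}")
    if k > len(window):
        raise InputError(f"k={k} exceeds window length {len(window)}")
    kmers = ["".join(p) for p in product(ALPHABET, repeat=k)]
    index = {m: i for i, m in enumerate(kmers)}
    out = np.zeros(4**k)
    n = len(window) - k + 1
    for i in range(n):
        sub = window[i : i + k]
        if sub not in index:
            raise InputError(f"window contains non-ACGU symbols: {sub!r}")
        out[index[sub]] += 1
    return out / n


def _profiles(window: str, table: PropertyTable) -> np.ndarray:
    """Property profiles over the window's dinucleotides, shape (n_props, L-1)."""
    if not table.standardized:
        raise InputError("property table must be standardized before encoding")
    if len(window) < 2:
        raise InputError("window too short for dinucleotides")
    try:
        cols = [DINUC_INDEX[window[i : i + 2]] for i in range(len(window) - 1)]
    except KeyError as exc:
        raise InputError(f"window contains non-ACGU symbols: {exc}") from exc
    return table.values[:, cols]


def _check_lag(g: int, n_dinuc: int) -> None:
    if not 1 <= g <= n_dinuc - 1:
        raise InputError(
            f"lag {g} out of range: need 1 <= g <= {n_dinuc - 1} so at least one summand remains"
        )


def auto_covariance(window: str, m: int, g: int, table: PropertyTable) -> float:
    """AC(m, g): lag-g autocovariance of property ``m`` (0-based index)."""
    prof = _profiles(window, table)
    _check_lag(g, prof.shape[1])
    dev = prof[m] - prof[m].mean()
    return float(dev[:-g] @ dev[g:] / (prof.shape[1] - g))


def cross_covariance(window: str, mu1: int, mu2: int, g: int, table: PropertyTable) -> float:
    """CC(mu1, mu2, g): lag-g covariance between two distinct properties."""
    if mu1 == mu2:
        raise InputError(f"cross-covariance requires two distinct properties, got {mu1} twice")
    prof = _profiles(window, table)
    _check_lag(g, prof.shape[1])
    d1 = prof[mu1] - prof[mu1].mean()
    d2 = prof[mu2] - prof[mu2].mean()
    return float(d1[:-g] @ d2[g:] / (prof.shape[1] - g))


def encode(
    window: str,
    table: PropertyTable,
    lam: int = DEFAULT_LAM,
    include_kmer: bool = False,
    k: int = 2,
) -> np.ndarray:
    """The pseudo-component feature vector of one window.

    Layout (lag-major): AC block of 10*lam components, then CC block of
    90*lam components over ordered property pairs; 100*lam total (500 at
    lam=5).  When ``include_kmer`` is set, the 4**k k-mer composition is
    appended.
    """
    n_dinuc = len(window) - 1
    if lam < 1:
        raise InputError(f"lam must be >= 1, got {lam}")
    if lam > n_dinuc - 1:
        raise InputError(f"lam={lam} too large for window length {len(window)} (need lam <= L-2)")
    prof = _profiles(window, table)
    centered = prof - prof.mean(axis=1, keepdims=True)
    n_props = prof.shape[0]
    pairs = list(permutations(range(n_props), 2))  # lexicographic (mu1, mu2)
    ac = np.empty((lam, n_props))
    cc = np.empty((lam, len(pairs)))
    for g in range(1, lam + 1):
        # (n_props x n_props) lagged covariance matrix; diagonal is AC
        cov = centered[:, :-g] @ centered[:, g:].T / (n_dinuc - g)
        ac[g - 1] = np.diag(cov)
        cc[g - 1] = cov[tuple(zip(*pairs))]
    vec = np.concatenate([ac.ravel(), cc.ravel()])
    if include_kmer:
        vec = np.concatenate([vec, kmer_composition(window, k)])
    if not np.all(np.isfinite(vec)):
        raise InputError("non-finite feature components")
    return vec


def feature_dim(lam: int, n_properties: int = 10, include_kmer: bool = False, k: int = 2) -> int:
    """Number of feature components for a configuration."""
    base = lam * n_properties * n_properties  # 10*lam AC + 90*lam CC = 100*lam
    return base + (4**k if include_kmer else 0)


class PseDncEncoder(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer from C-centered windows to pseudo-component vectors.

    Parameters
    ----------
    lam : int, default=5
        Maximum dinucleotide lag; the vector has 100*lam covariance
        components.
    include_kmer : bool, default=False
        Append the 4**k k-mer composition block.
    k : int, default=2
        k-mer order for the optional block.
    property_table : PropertyTable, str path, or None, default=None
        Source of physical-chemical values; None loads the packaged default
        table.  Standardization is applied at fit time.

    Attributes
    ----------
    table_ : PropertyTable
        The standardized property table used for encoding.
    n_features_out_ : int
        Dimension of the output vectors.
    property_checksum_ : str
        Checksum of ``table_``; recorded in saved models.
    """

    def __init__(
        self,
        lam: int = DEFAULT_LAM,
        include_kmer: bool = False,
        k: int = 2,
        property_table: PropertyTable | str | None = None,
    ) -> None:
        self.lam = lam
        self.include_kmer = include_kmer
        self.k = k
        self.property_table = property_table

    def fit(self, X: Iterable[str] | None = None, y=None) -> "PseDncEncoder":
        """Load and standardize the property table; X is not inspected."""
        if isinstance(self.property_table, PropertyTable):
            table = self.property_table
        else:
            table = load_property_table(self.property_table)
        self.table_ = table if table.standardized else standardize(table)
        self.n_features_out_ = feature_dim(
            self.lam, self.table_.n_properties, self.include_kmer, self.k
        )
        self.property_checksum_ = self.table_.checksum()
        self.layout_version_ = LAYOUT_VERSION
        return self

    def transform(self, X: Iterable[str]) -> np.ndarray:
        """Encode an iterable of equal-length window strings to a matrix."""
        check_is_fitted(self, "table_")
        windows = [w.window if hasattr(w, "window") else str(w) for w in X]
        if not windows:
            raise InputError("no windows to encode")
        lengths = {len(w) for w in windows}
        if len(lengths) != 1:
            raise InputError(f"mixed window lengths: {sorted(lengths)}")
        return np.vstack(
            [encode(w, self.table_, self.lam, self.include_kmer, self.k) for w in windows]
        )


def encode_dataset(
    dataset: BenchmarkDataset,
    encoder: PseDncEncoder | None = None,
    **encoder_params,
) -> tuple[np.ndarray, np.ndarray, PseDncEncoder]:
    """Encode a benchmark: rows are positives (input order) then negatives.

    Returns (X, y, fitted encoder) with y[i] = 1 for positive windows.
    """
    if len(dataset) == 0:
        raise InputError("empty dataset")
    if encoder is None:
        encoder = PseDncEncoder(**encoder_params)
    if not hasattr(encoder, "table_"):
        encoder.fit()
    windows = dataset.windows
    X = encoder.transform([w.window for w in windows])
    y = np.array([1 if w.label == POSITIVE else 0 for w in windows])
    return X, y, encoder
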