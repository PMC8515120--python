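"""¹H-NMR spectral preprocessing for urine metabolomics.

The workflow mirrors standard cohort urine NMR practice: probabilistic
quotient normalisation (PQN) to undo per-sample dilution, statistical
recoupling of variables (SRV) to segment the chemical-shift axis into
quantifiable peak clusters, targeted trapezoidal integration of named
multiplet regions (hippurate by default), and creatinine adjustment of
the resulting feature table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "SpectraMatrix",
    "PeakCluster",
    "PeakClusterSet",
    "FeatureTable",
    "PQNNormalizer",
    "SRVClusterer",
    "pqn_normalize",
    "srv_cluster",
    "integrate_regions",
    "creatinine_adjust",
    "HIPPURATE_CENTERS",
    "hippurate_regions",
]

#: Chemical shifts (ppm) of the three hippurate aromatic multiplets:
#: doublet at 7.84, triplets at 7.64 and 7.55 ppm.
HIPPURATE_CENTERS = (7.84, 7.64, 7.55)

#: Spectral windows excluded from the PQN quotient region by default:
#: residual water (4.5-5.0 ppm) and the TSP reference (±0.05 ppm around 0).
DEFAULT_EXCLUDED_WINDOWS = ((4.5, 5.0), (-0.05, 0.05))


def hippurate_regions(half_width: float = 0.03) -> list[tuple[float, float]]:
    """Integration windows centred on the three hippurate multiplets."""
    return [(c - half_width, c + half_width) for c in HIPPURATE_CENTERS]


@dataclass
class SpectraMatrix:
    """A cohort of 1D spectra on a shared chemical-shift axis.

    Parameters
    ----------
    ppm
        Strictly monotone chemical-shift axis (conventionally descending).
    intensities
        ``(n_subjects, n_points)`` array of intensities, arbitrary units.
    subject_ids
        One identifier per row.
    """

    ppm: np.ndarray
    intensities: np.ndarray
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.ppm.ndim != 1:
            raise ValueError("ppm axis must be one-dimensional")
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")
        if self.intensities.shape[1] != self.ppm.size:
            raise ValueError(
                f"intensity columns ({self.intensities.shape[1]}) do not match "
                f"ppm axis length ({self.ppm.size})"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if not self.subject_ids:
            self.subject_ids = [f"S{i:04d}" for i in range(self.n_subjects)]
        if len(self.subject_ids) != self.n_subjects:
            raise ValueError("subject_ids length does not match number of spectra")

    @property
    def n_subjects(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.ppm.size

    def with_intensities(self, intensities: np.ndarray) -> "SpectraMatrix":
        return replace(self, intensities=np.asarray(intensities, dtype=float))

    def index_of(self, ppm_value: float) -> int:
        """Index of the axis point closest to ``ppm_value``."""
        return int(np.argmin(np.abs(self.ppm - ppm_value)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intensities, index=self.subject_ids, columns=self.ppm)


@dataclass(frozen=True)
class PeakCluster:
    start_index: int
    end_index: int  # inclusive
    apex_ppm: float

    @property
    def size(self) -> int:
        return self.end_index - self.start_index + 1


@dataclass
class PeakClusterSet:
    """Ordered, non-overlapping peak clusters on a spectral axis."""

    clusters: list[PeakCluster]
    min_size: int
    merge_threshold: float

    def __post_init__(self) -> None:
        for c in self.clusters:
            if c.start_index > c.end_index:
                raise ValueError("cluster with start_index > end_index")
            if c.size < self.min_size:
                raise ValueError("cluster shorter than min_size")
        for a, b in zip(self.clusters, self.clusters[1:]):
            if b.start_index <= a.end_index:
                raise ValueError("clusters overlap or are unsorted")

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def integrate(self, spectra: SpectraMatrix) -> "FeatureTable":
        """Trapezoidal integral of every cluster for every subject."""
        axis = np.abs(spectra.ppm)  # widths in ppm, independent of axis direction
        values = np.empty((spectra.n_subjects, len(self.clusters)))
        meta = []
        for j, c in enumerate(self.clusters):
            sl = slice(c.start_index, c.end_index + 1)
            x = spectra.ppm[sl]
            order = np.argsort(x)
            values[:, j] = np.trapezoid(spectra.intensities[:, sl][:, order], x[order], axis=1)
            meta.append(
                {
                    "cluster_id": f"C{j:04d}",
                    "apex_ppm": c.apex_ppm,
                    "start_index": c.start_index,
                    "end_index": c.end_index,
                }
            )
        table = pd.DataFrame(
            values, index=spectra.subject_ids, columns=[m["cluster_id"] for m in meta]
        )
        return FeatureTable(values=table, metadata=pd.DataFrame(meta).set_index("cluster_id"))


@dataclass
class FeatureTable:
    """Subjects × peak-cluster integrals plus per-cluster metadata."""

    values: pd.DataFrame
    metadata: pd.DataFrame
    creatinine_adjusted: bool = False

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("feature integrals must be finite")
        if not self.values.columns.equals(self.metadata.index):
            raise ValueError("metadata index must match feature columns")


class PQNNormalizer(TransformerMixin, BaseEstimator):
    """Probabilistic quotient normalisation of 1D spectra.

    Each spectrum is divided by the median of its pointwise quotients to a
    reference spectrum over a quantification region, which removes a
    per-sample multiplicative dilution factor (the dominant nuisance in
    urine NMR).

    Parameters
    ----------
    reference : "median" or array-like
        Reference spectrum; ``"median"`` uses the pointwise median across
        the fitted cohort (requires ≥ 2 spectra).
    excluded_windows : sequence of (ppm_lo, ppm_hi)
        Axis windows excluded from the quotient region (water and the TSP
        reference by default).

    Attributes
    ----------
    reference_ : ndarray
        Reference spectrum used for the quotients.
    region_mask_ : ndarray of bool
        Points of the axis entering the quotient median.
    dilution_factors_ : ndarray
        Median quotient per fitted spectrum (the estimated dilutions).
    """

    def __init__(self, reference="median", excluded_windows=DEFAULT_EXCLUDED_WINDOWS):
        self.reference = reference
        self.excluded_windows = excluded_windows

    def fit(self, spectra: SpectraMatrix, y=None):
        X = spectra.intensities
        if isinstance(self.reference, str):
            if self.reference != "median":
                raise ValueError(f"unknown reference rule {self.reference!r}")
            if spectra.n_subjects < 2:
                raise ValueError("median reference requires at least 2 spectra")
            ref = np.median(X, axis=0)
        else:
            ref = np.asarray(self.reference, dtype=float)
            if ref.shape != (spectra.n_points,):
                raise ValueError("supplied reference length does not match axis")
        mask = np.ones(spectra.n_points, dtype=bool)
        for lo, hi in self.excluded_windows:
            mask &= ~((spectra.ppm >= lo) & (spectra.ppm <= hi))
        mask &= ref > 0
        if not mask.any():
            raise ValueError("reference is non-positive over the entire quotient region")
        self.reference_ = ref
        self.region_mask_ = mask
        return self

    def transform(self, spectra: SpectraMatrix) -> SpectraMatrix:
        X = spectra.intensities
        quotients = X[:, self.region_mask_] / self.reference_[self.region_mask_]
        factors = np.median(quotients, axis=1)
        bad = ~(factors > 0)
        if bad.any():
            names = [spectra.subject_ids[i] for i in np.flatnonzero(bad)]
            raise ValueError(
                "undefined PQN quotient (non-positive median) for subjects: "
                + ", ".join(names)
            )
        self.dilution_factors_ = factors
        return spectra.with_intensities(X / factors[:, None])


def pqn_normalize(
    spectra: SpectraMatrix,
    reference="median",
    excluded_windows=DEFAULT_EXCLUDED_WINDOWS,
) -> SpectraMatrix:
    """PQN-normalise a cohort of spectra (cohort-median reference by default)."""
    return PQNNormalizer(reference, excluded_windows).fit(spectra).transform(spectra)


class SRVClusterer(BaseEstimator):
    """Statistical recoupling of variables (SRV) peak clustering.

    Adjacent spectral variables belonging to one resonance co-vary across
    subjects. SRV scans the axis with the landscape ``cov/corr`` of each
    adjacent variable pair, cuts segments at local minima of that
    landscape, discards segments shorter than ``min_size`` (noise), and
    merges adjacent segments whose representative signals (mean segment
    intensity per subject) correlate above ``merge_threshold``
    (superclusters, i.e. multiplets split by the landscape).

    Attributes
    ----------
    clusters_ : PeakClusterSet
    landscape_ : ndarray of shape (n_points - 1,)
    """

    def __init__(self, min_size: int = 5, merge_threshold: float = 0.9):
        self.min_size = min_size
        self.merge_threshold = merge_threshold

    def fit(self, spectra: SpectraMatrix, y=None):
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if not 0.0 <= self.merge_threshold <= 1.0:
            raise ValueError("merge_threshold must be in [0, 1]")
        X = spectra.intensities
        if X.shape[0] < 2:
            raise ValueError("SRV requires at least 2 spectra")
        Xc = X - X.mean(axis=0)
        sd = X.std(axis=0)
        cov = np.einsum("ij,ij->j", Xc[:, :-1], Xc[:, 1:]) / X.shape[0]
        denom = sd[:-1] * sd[1:]
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(denom > 0, cov / denom, 0.0)
            # landscape = cov/corr = sd_i * sd_{i+1}; undefined (constant
            # column) pairs get 0 and thus act as segment boundaries
            landscape = np.where(np.abs(corr) > 1e-12, cov / corr, 0.0)
        self.landscape_ = landscape

        boundaries = self._local_minima(landscape)
        segments = []
        start = 0
        for b in boundaries:
            # landscape index b sits between variables b and b+1: cut there
            segments.append((start, b))
            start = b + 1
        segments.append((start, X.shape[1] - 1))
        segments = [s for s in segments if s[1] - s[0] + 1 >= self.min_size]
        segments = self._merge(segments, X)

        mean_spec = X.mean(axis=0)
        clusters = []
        for s, e in segments:
            apex = s + int(np.argmax(mean_spec[s : e + 1]))
            clusters.append(PeakCluster(s, e, float(spectra.ppm[apex])))
        self.clusters_ = PeakClusterSet(clusters, self.min_size, self.merge_threshold)
        return self

    @staticmethod
    def _local_minima(landscape: np.ndarray) -> np.ndarray:
        v = landscape
        if v.size < 3:
            return np.array([], dtype=int)
        interior = np.arange(1, v.size - 1)
        is_min = (v[interior] < v[interior - 1]) & (v[interior] <= v[interior + 1])
        return interior[is_min]

    def _merge(self, segments, X):
        """Merge adjacent segments with strongly correlated representatives."""
        merged = []
        for seg in segments:
            if merged:
                prev = merged[-1]
                if seg[0] == prev[1] + 1:  # only contiguous segments can be one multiplet
                    a = X[:, prev[0] : prev[1] + 1].mean(axis=1)
                    b = X[:, seg[0] : seg[1] + 1].mean(axis=1)
                    if a.std() > 0 and b.std() > 0:
                        r = np.corrcoef(a, b)[0, 1]
                        if r > self.merge_threshold:
                            merged[-1] = (prev[0], seg[1])
                            continue
            merged.append(seg)
        return merged


def srv_cluster(
    spectra: SpectraMatrix, min_size: int = 5, corr_threshold: float = 0.9
) -> PeakClusterSet:
    """Segment a spectral axis into SRV peak clusters."""
    return SRVClusterer(min_size=min_size, merge_threshold=corr_threshold).fit(spectra).clusters_


def integrate_regions(
    spectra: SpectraMatrix, regions: list[tuple[float, float]] | None = None
) -> np.ndarray:
    """Summed trapezoidal area of named ppm windows, one value per subject.

    ``regions=None`` integrates the three hippurate multiplet windows
    (7.84, 7.64, 7.55 ppm ± 0.03) and sums them, which is the targeted
    hippurate quantification used throughout the cohort analysis.
    """
    if regions is None:
        regions = hippurate_regions()
    lo_axis, hi_axis = float(np.min(spectra.ppm)), float(np.max(spectra.ppm))
    total = np.zeros(spectra.n_subjects)
    for lo, hi in regions:
        if lo > hi:
            lo, hi = hi, lo
        if lo < lo_axis or hi > hi_axis:
            raise ValueError(
                f"region ({lo:.3f}, {hi:.3f}) ppm outside spectral axis "
                f"[{lo_axis:.3f}, {hi_axis:.3f}]"
            )
        sel = (spectra.ppm >= lo) & (spectra.ppm <= hi)
        x = spectra.ppm[sel]
        order = np.argsort(x)
        total += np.trapezoid(spectra.intensities[:, sel][:, order], x[order], axis=1)
    return total


def creatinine_adjust(features: FeatureTable, creatinine: np.ndarray) -> FeatureTable:
    """Divide every feature by the subject's creatinine value.

    Creatinine excretion scales with muscle mass and urine concentration;
    dividing by it expresses metabolite integrals per unit creatinine, the
    conventional urine normaliser.
    """
    creatinine = np.asarray(creatinine, dtype=float)
    if creatinine.shape != (len(features.values),):
        raise ValueError("creatinine vector length does not match feature table")
    bad = ~(creatinine > 0)
    if bad.any():
        names = [str(features.values.index[i]) for i in np.flatnonzero(bad)]
        raise ValueError("non-positive creatinine for subjects: " + ", ".join(names))
    return FeatureTable(
        values=features.values.div(creatinine, axis=0),
        metadata=features.metadata,
        creatinine_adjusted=True,
    )
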