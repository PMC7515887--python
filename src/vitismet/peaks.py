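"""Peak-list containers, ppm-tolerance alignment and the intensity preprocessing chain.

Direct-infusion FT-ICR mass spectra arrive as per-sample peak lists
(m/z, intensity).  This module aligns them into a features x samples
matrix and applies the standard preprocessing sequence for such data:

    aligned -> filtered -> imputed -> normalized -> glog -> pareto

Stage order is enforced: each step checks the stage of its input and
raises :class:`StageError` when run out of order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Preprocessing stages in their mandatory order.
STAGES = ("aligned", "filtered", "imputed", "normalized", "glog", "pareto")

MODES = ("positive", "negative")

RESISTANT = "resistant_partial_resistant"
SUSCEPTIBLE = "susceptible"


class StageError(RuntimeError):
    """A preprocessing step was applied to a matrix in the wrong stage."""


class MissingStandardError(ValueError):
    """No feature matches the internal-standard m/z within tolerance."""


class AmbiguousStandardError(ValueError):
    """More than one feature matches the internal-standard m/z within tolerance."""


def ppm_gap(a: float, b: float) -> float:
    """Relative m/z difference in ppm, referenced to the smaller of the two masses."""
    lo = min(a, b)
    if lo <= 0:
        raise ValueError("m/z values must be positive")
    return abs(a - b) / lo * 1e6


def ppm_error(measured: float, theoretical: float) -> float:
    """Signed ppm deviation of a measured m/z against a theoretical reference mass."""
    return (measured - theoretical) / theoretical * 1e6


@dataclass(frozen=True)
class PeakList:
    """One sample's centroided peaks from one ionization mode.

    Peaks are sorted canonically by m/z on construction; intensities must
    be strictly positive.  Peak picking (e.g. the S/N >= 4 threshold of
    vendor software) is assumed to have happened upstream.
    """

    sample_id: str
    mz: np.ndarray
    intensity: np.ndarray
    ionization_mode: str = "positive"

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.ndim != 1 or inten.shape != mz.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.ionization_mode not in MODES:
            raise ValueError(f"ionization_mode must be one of {MODES}")
        if np.any(inten <= 0):
            raise ValueError("intensities must be strictly positive")
        if np.any(mz <= 0):
            raise ValueError("m/z values must be strictly positive")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensity", inten[order])

    def __len__(self) -> int:
        return self.mz.size


@dataclass
class FeatureMatrix:
    """Aligned features x samples intensity table with a processing stage tag.

    ``data`` is indexed by the representative feature m/z (strictly
    increasing) with one column per sample; missing peaks are NaN until
    the imputation stage.  ``events`` accumulates a human-readable log of
    collisions, drops and degenerate-row guards.
    """

    data: pd.DataFrame
    stage: str
    ionization_mode: str
    events: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.ionization_mode not in MODES:
            raise ValueError(f"ionization_mode must be one of {MODES}")
        mz = self.data.index.to_numpy(dtype=float)
        if mz.size > 1 and np.any(np.diff(mz) <= 0):
            raise ValueError("feature m/z index must be strictly increasing")

    @property
    def feature_mz(self) -> np.ndarray:
        return self.data.index.to_numpy(dtype=float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def require_stage(self, stage: str) -> None:
        if self.stage != stage:
            raise StageError(
                f"operation requires stage {stage!r} but matrix is at {self.stage!r}"
            )

    def _advance(self, data: pd.DataFrame, stage: str, events: list[str]) -> "FeatureMatrix":
        if STAGES.index(stage) != STAGES.index(self.stage) + 1:
            raise StageError(f"cannot advance from {self.stage!r} to {stage!r}")
        return FeatureMatrix(
            data=data,
            stage=stage,
            ionization_mode=self.ionization_mode,
            events=self.events + events,
        )


def validate_metadata(meta: pd.DataFrame, sample_ids: list[str]) -> pd.DataFrame:
    """Check a sample-metadata table against a matrix's sample set.

    Requires columns ``sample_id``, ``genotype``, ``replicate``, ``group``;
    every sample must have exactly one row and each genotype must map to a
    single resistance group.
    """
    required = {"sample_id", "genotype", "replicate", "group"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata missing columns: {sorted(missing_cols)}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    absent = set(sample_ids) - set(meta["sample_id"])
    if absent:
        raise ValueError(f"metadata missing samples: {sorted(absent)}")
    per_geno = meta.groupby("genotype")["group"].nunique()
    if (per_geno > 1).any():
        bad = per_geno[per_geno > 1].index.tolist()
        raise ValueError(f"genotypes mapped to more than one group: {bad}")
    return meta.set_index("sample_id").loc[sample_ids].reset_index()


def align_peaklists(lists: list[PeakList], ppm_tol: float = 1.0) -> FeatureMatrix:
    """Align per-sample peak lists into a feature matrix by ppm-gap clustering.

    All peaks are pooled and sorted by m/z; features are maximal runs in
    which every consecutive pair of peaks differs by <= ``ppm_tol`` ppm
    (single-linkage gap rule), so the result does not depend on the order
    in which samples are supplied.  The representative feature m/z is the
    intensity-weighted mean of the member peaks.  When one sample
    contributes several peaks to one feature the most intense peak wins
    and the collision is logged.
    """
    if not lists:
        raise ValueError("no peak lists supplied")
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be positive")
    modes = {pl.ionization_mode for pl in lists}
    if len(modes) > 1:
        raise ValueError(f"mixed ionization modes: {sorted(modes)}")
    sample_ids = [pl.sample_id for pl in lists]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample_id among peak lists")

    mz = np.concatenate([pl.mz for pl in lists])
    inten = np.concatenate([pl.intensity for pl in lists])
    samp = np.concatenate(
        [np.full(len(pl), i, dtype=int) for i, pl in enumerate(lists)]
    )
    order = np.argsort(mz, kind="stable")
    mz, inten, samp = mz[order], inten[order], samp[order]

    # split where the gap between consecutive sorted peaks exceeds the tolerance
    gaps = (mz[1:] - mz[:-1]) / mz[:-1] * 1e6
    breaks = np.flatnonzero(gaps > ppm_tol) + 1
    starts = np.concatenate(([0], breaks))
    stops = np.concatenate((breaks, [mz.size]))

    events: list[str] = []
    rep_mz = np.empty(starts.size)
    values = np.full((starts.size, len(lists)), np.nan)
    for f, (a, b) in enumerate(zip(starts, stops)):
        w = inten[a:b]
        rep_mz[f] = np.average(mz[a:b], weights=w)
        for j in range(a, b):
            s = samp[j]
            if not math.isnan(values[f, s]):
                events.append(
                    f"collision: sample {sample_ids[s]} has multiple peaks in "
                    f"feature {rep_mz[f]:.6f}; kept max intensity"
                )
                values[f, s] = max(values[f, s], inten[j])
            else:
                values[f, s] = inten[j]

    data = pd.DataFrame(values, index=pd.Index(rep_mz, name="mz"), columns=sample_ids)
    return FeatureMatrix(data=data, stage="aligned",
                         ionization_mode=lists[0].ionization_mode, events=events)


def filter_by_occurrence(
    m: FeatureMatrix,
    meta: pd.DataFrame,
    fraction: float = 2 / 3,
    strict: bool = False,
) -> FeatureMatrix:
    """Keep features observed in enough replicates of at least one genotype.

    Default rule: a feature passes for a genotype with ``n`` replicates if
    it is observed in >= ceil(fraction * n) of them (2 of 3 at the default
    two-thirds fraction).  ``strict=True`` applies the literal
    strictly-greater reading (count > fraction * n, i.e. 3 of 3).
    """
    m.require_stage("aligned")
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    meta = validate_metadata(meta, m.sample_ids)

    keep = np.zeros(m.n_features, dtype=bool)
    for genotype, rows in meta.groupby("genotype"):
        cols = rows["sample_id"].tolist()
        n = len(cols)
        counts = m.data[cols].notna().sum(axis=1).to_numpy()
        if strict:
            keep |= counts > fraction * n
        else:
            keep |= counts >= math.ceil(fraction * n)

    dropped = int((~keep).sum())
    events = [f"occurrence filter: dropped {dropped} of {m.n_features} features "
              f"(fraction={fraction:.4g}, strict={strict})"]
    return m._advance(m.data.loc[keep], "filtered", events)


def impute_half_global_min(m: FeatureMatrix) -> FeatureMatrix:
    """Replace missing cells by half the global minimum observed intensity."""
    m.require_stage("filtered")
    observed = m.data.to_numpy()
    if np.all(np.isnan(observed)):
        raise ValueError("matrix has no observed cells")
    fill = np.nanmin(observed) / 2.0
    n_missing = int(np.isnan(observed).sum())
    data = m.data.fillna(fill)
    return m._advance(data, "imputed",
                      [f"imputation: {n_missing} missing cells set to {fill:.6g}"])


def normalize_by_internal_standard(
    m: FeatureMatrix, standard_mz: float, ppm_tol: float = 1.0
) -> FeatureMatrix:
    """Divide each sample by its internal-standard intensity; drop the standard.

    The standard feature is located by ppm deviation against the
    theoretical ``standard_mz``.  Absence and ambiguity (two features in
    tolerance) are distinct errors.
    """
    m.require_stage("imputed")
    dev = np.abs((m.feature_mz - standard_mz) / standard_mz * 1e6)
    hits = np.flatnonzero(dev <= ppm_tol)
    if hits.size == 0:
        raise MissingStandardError(
            f"no feature within {ppm_tol} ppm of standard m/z {standard_mz:.6f}"
        )
    if hits.size > 1:
        raise AmbiguousStandardError(
            f"{hits.size} features within {ppm_tol} ppm of standard m/z "
            f"{standard_mz:.6f}: {m.feature_mz[hits].round(6).tolist()}"
        )
    std_row = m.data.iloc[hits[0]]
    if (std_row <= 0).any() or std_row.isna().any():
        raise MissingStandardError("standard feature not observed in every sample")
    data = m.data.div(std_row, axis=1).drop(index=m.data.index[hits[0]])
    return m._advance(
        data, "normalized",
        [f"normalized by standard feature at m/z {m.feature_mz[hits[0]]:.6f}"],
    )


def glog(x, lam: float):
    """Elementwise generalized log: log2((x + sqrt(x^2 + lam^2)) / 2).

    Behaves like log2(x) for x >> lam and linearly near zero; lam = 0
    reduces exactly to log2.
    """
    if lam < 0:
        raise ValueError("lam must be non-negative")
    x = np.asarray(x, dtype=float)
    return np.log2((x + np.sqrt(x * x + lam * lam)) / 2.0)


def glog_transform(m: FeatureMatrix, lam: float | None = None) -> FeatureMatrix:
    """Apply the generalized log transform to a normalized matrix.

    Default lam is half the smallest positive intensity in the matrix, a
    conventional variance-stabilizing choice when no external estimate of
    the additive-noise scale is available.
    """
    m.require_stage("normalized")
    values = m.data.to_numpy()
    if np.any(values <= 0):
        raise ValueError("glog stage requires strictly positive intensities")
    if lam is None:
        lam = float(values.min()) / 2.0
    if lam < 0:
        raise ValueError("lam must be non-negative")
    data = pd.DataFrame(glog(values, lam), index=m.data.index, columns=m.data.columns)
    return m._advance(data, "glog", [f"glog transform with lambda={lam:.6g}"])


def pareto_scale(m: FeatureMatrix) -> FeatureMatrix:
    """Center each feature and divide by the square root of its sample SD.

    Zero-variance features become all-zero rows; each such guard is
    logged and a warning is issued.
    """
    m.require_stage("glog")
    if m.n_samples < 2:
        raise ValueError("Pareto scaling requires at least 2 samples")
    values = m.data.to_numpy()
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    centered = values - mean
    out = np.zeros_like(centered)
    nonzero = sd[:, 0] > 0
    out[nonzero] = centered[nonzero] / np.sqrt(sd[nonzero])
    events = []
    n_const = int((~nonzero).sum())
    if n_const:
        events.append(f"pareto: {n_const} zero-variance features set to all-zero rows")
        warnings.warn(f"{n_const} zero-variance features zeroed during Pareto scaling")
    data = pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    return m._advance(data, "pareto", events)


def preprocess_chain(
    lists: list[PeakList],
    meta: pd.DataFrame,
    ppm_align: float = 1.0,
    occurrence_fraction: float = 2 / 3,
    strict_occurrence: bool = False,
    standard_mz: float | None = None,
    ppm_standard: float = 1.0,
    lam: float | None = None,
) -> dict[str, FeatureMatrix]:
    """Run align -> filter -> impute -> normalize -> glog -> pareto.

    Returns the matrix at every stage keyed by stage name; the
    normalization step is skipped (with a log entry) when ``standard_mz``
    is None, in which case the imputed matrix is re-tagged as normalized.
    """
    out: dict[str, FeatureMatrix] = {}
    out["aligned"] = align_peaklists(lists, ppm_tol=ppm_align)
    out["filtered"] = filter_by_occurrence(
        out["aligned"], meta, fraction=occurrence_fraction, strict=strict_occurrence
    )
    out["imputed"] = impute_half_global_min(out["filtered"])
    if standard_mz is None:
        m = out["imputed"]
        out["normalized"] = FeatureMatrix(
            data=m.data.copy(), stage="normalized", ionization_mode=m.ionization_mode,
            events=m.events + ["normalization skipped: no internal standard configured"],
        )
    else:
        out["normalized"] = normalize_by_internal_standard(
            out["imputed"], standard_mz, ppm_tol=ppm_standard
        )
    out["glog"] = glog_transform(out["normalized"], lam=lam)
    out["pareto"] = pareto_scale(out["glog"])
    return out


# ---------------------------------------------------------------------------
# plain-text I/O

def write_peaklist(pl: PeakList, path) -> None:
    """Write a peak list as a two-column TSV (mz, intensity)."""
    pd.DataFrame({"mz": pl.mz, "intensity": pl.intensity}).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_peaklist(path, sample_id: str, ionization_mode: str = "positive") -> PeakList:
    df = pd.read_csv(path, sep="\t")
    return PeakList(sample_id=sample_id, mz=df["mz"].to_numpy(),
                    intensity=df["intensity"].to_numpy(),
                    ionization_mode=ionization_mode)


def write_feature_matrix(m: FeatureMatrix, path) -> None:
    """Write a feature matrix as TSV with a stage/mode header comment."""
    with open(path, "w") as fh:
        fh.write(f"# stage={m.stage} ionization_mode={m.ionization_mode}\n")
        out = m.data.copy()
        out.index = [f"{v:.6f}" for v in out.index]
        out.index.name = "mz"
        out.to_csv(fh, sep="\t")


def read_feature_matrix(path) -> FeatureMatrix:
    with open(path) as fh:
        header = fh.readline().strip()
        fields = dict(part.split("=") for part in header.lstrip("# ").split())
        data = pd.read_csv(fh, sep="\t", index_col=0)
    data.index = data.index.astype(float)
    data.index.name = "mz"
    return FeatureMatrix(data=data, stage=fields["stage"],
                         ionization_mode=fields["ionization_mode"])
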