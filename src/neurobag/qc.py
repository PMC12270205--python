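"""Multi-layered volume quality control.

Three detectors, each applied separately within every subgroup stratum so
that flags reflect anomalies relative to the scan's own clinical context:

1. intensity screening on raw volumes - robust z-scores (median/MAD) of
   each scan's global mean intensity, intensity SD, and standardized
   extreme value;
2. PCA + Mahalanobis distance on flattened normalized volumes - scans
   whose squared distance in component space exceeds a chi-square
   quantile are flagged;
3. Isolation Forest on the same PCA score representation, flagging a
   fixed contamination quota.

The union of flags is marked for manual review; flag sets are
deterministic given the seed and thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import IsolationForest

log = logging.getLogger(__name__)


@dataclass
class QCConfig:
    z_thresh: float = 3.0
    extreme_z_thresh: float = 6.0     # cohort-standardized voxel extremes
    variance_retained: float = 0.95
    max_components: int = 10          # stability cap on retained components
    chi2_quantile: float = 0.999
    contamination: float = 0.02
    min_subgroup_n: int = 10
    seed: int = 0


@dataclass
class QCReport:
    """Per-scan QC flags and scores, plus the thresholds that produced them."""

    table: pd.DataFrame          # one row per scan
    thresholds: dict = field(default_factory=dict)

    @property
    def flagged(self) -> pd.Series:
        return self.table.loc[self.table["flagged"], "scan_id"]

    def to_json_summary(self) -> dict:
        t = self.table
        return {
            "n_scans": int(len(t)),
            "n_flagged": int(t["flagged"].sum()),
            "by_detector": {d: int(t[f"flag_{d}"].sum())
                            for d in ("intensity", "mahalanobis", "isoforest")},
            "thresholds": self.thresholds,
        }


def _robust_z(values: np.ndarray) -> np.ndarray:
    med = np.median(values)
    mad = stats.median_abs_deviation(values, scale="normal")
    if mad == 0:
        # zero-spread fallback: any exact deviation from the median is flagged
        return np.where(values == med, 0.0, np.inf)
    return (values - med) / mad


def intensity_outliers(volumes, scan_ids=None, z_thresh: float = 3.0,
                       extreme_z_thresh: float = 6.0) -> pd.DataFrame:
    """Flag scans whose global intensity statistics diverge from the stratum.

    Two criteria: (1) robust z-scores (median/MAD) of each scan's mean
    intensity and intensity SD against the stratum, thresholded at
    ``z_thresh``; (2) voxel intensities standardized by the stratum's
    typical center and spread - a scan containing voxels beyond
    ``extreme_z_thresh`` falls significantly outside the expected range.
    """
    vols = [np.asarray(getattr(v, "voxels", v), dtype=float) for v in volumes]
    if len(vols) < 3:
        raise ValueError("intensity screening needs at least 3 volumes")
    if scan_ids is None:
        scan_ids = [f"scan{i:04d}" for i in range(len(vols))]
    means = np.array([v.mean() for v in vols])
    sds = np.array([v.std() for v in vols])
    z_mean, z_sd = _robust_z(means), _robust_z(sds)
    center = np.median(means)
    spread = np.median(sds)
    if spread > 0:
        z_ext = np.array([np.max(np.abs(v - center)) / spread for v in vols])
    else:
        z_ext = np.zeros(len(vols))
    with np.errstate(invalid="ignore"):
        flagged = (np.abs(z_mean) > z_thresh) | (np.abs(z_sd) > z_thresh) | \
                  (z_ext > extreme_z_thresh)
    return pd.DataFrame({
        "scan_id": scan_ids, "mean_intensity": means, "sd_intensity": sds,
        "z_mean": z_mean, "z_sd": z_sd, "z_extreme": z_ext,
        "flag_intensity": flagged,
    })


def _pca_scores(vols: np.ndarray, variance_retained: float, max_components: int = 10):
    flat = vols.reshape(len(vols), -1)
    flat = flat - flat.mean(axis=0)
    k_max = min(len(vols) - 1, flat.shape[1])
    pca = PCA(n_components=k_max, svd_solver="full")
    scores = pca.fit_transform(flat)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_retained) + 1)
    # cap the dimension: with k approaching n, sample Mahalanobis
    # distances become nearly constant and the detector loses power
    k = min(max(k, 1), k_max, max_components)
    return scores[:, :k], pca.explained_variance_[:k]


def pca_mahalanobis_outliers(volumes, scan_ids=None, variance_retained: float = 0.95,
                             chi2_quantile: float = 0.999,
                             max_components: int = 10) -> pd.DataFrame:
    """Flag scans far from the multivariate center in PCA space.

    Squared Mahalanobis distances in the retained component space are
    compared against the chi-square quantile with k degrees of freedom.
    Near-zero component variances are diagonally loaded before inverting.
    """
    vols = np.asarray([np.asarray(getattr(v, "voxels", v), dtype=float) for v in volumes])
    if scan_ids is None:
        scan_ids = [f"scan{i:04d}" for i in range(len(vols))]
    scores, variances = _pca_scores(vols, variance_retained, max_components)
    k = scores.shape[1]
    if len(vols) < k + 2:
        raise ValueError(f"need n >= k+2 scans (n={len(vols)}, k={k})")
    floor = 1e-12 * max(variances.max(), 1.0)
    if (variances < floor).any():
        log.warning("singular component covariance; applying diagonal loading")
        variances = np.maximum(variances, floor)
    d2 = np.sum(scores ** 2 / variances, axis=1)
    if chi2_quantile >= 1.0:
        cut = np.inf
    else:
        cut = stats.chi2.ppf(chi2_quantile, df=k)
    return pd.DataFrame({
        "scan_id": scan_ids, "mahalanobis_d2": d2, "mahalanobis_df": k,
        "flag_mahalanobis": d2 > cut,
    })


def isoforest_outliers(volumes, scan_ids=None, contamination: float = 0.02,
                       seed: int = 0, variance_retained: float = 0.95,
                       max_components: int = 10) -> pd.DataFrame:
    """Flag the ceil(contamination * n) most isolable scans.

    Runs an Isolation Forest on the PCA score representation (the same
    feature space as the Mahalanobis stage); deterministic given seed.
    """
    if not (0 < contamination <= 0.5):
        raise ValueError("contamination must be in (0, 0.5]")
    vols = np.asarray([np.asarray(getattr(v, "voxels", v), dtype=float) for v in volumes])
    n = len(vols)
    if n < 10:
        raise ValueError("isolation forest needs at least 10 scans")
    if scan_ids is None:
        scan_ids = [f"scan{i:04d}" for i in range(n)]
    scores, _ = _pca_scores(vols, variance_retained, max_components)
    forest = IsolationForest(contamination="auto", random_state=seed)
    forest.fit(scores)
    anomaly = -forest.score_samples(scores)  # higher = more isolable
    quota = int(np.ceil(contamination * n))
    order = np.argsort(-anomaly, kind="stable")
    flags = np.zeros(n, dtype=bool)
    flags[order[:quota]] = True
    return pd.DataFrame({
        "scan_id": scan_ids, "isolation_score": anomaly, "flag_isoforest": flags,
    })


def export_review(report: "QCReport", cohort: pd.DataFrame, volumes,
                  out_dir, scan_col: str = "scan_id") -> list:
    """Export flagged scan IDs and central-slice thumbnails for manual review.

    Writes ``flagged_scans.csv`` plus one PNG of the three central
    orthogonal slices per flagged scan; returns the written paths.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    flagged = report.table[report.table["flagged"]]
    paths = [out / "flagged_scans.csv"]
    flagged.to_csv(paths[0], index=False)
    index = {sid: i for i, sid in enumerate(cohort[scan_col])}
    for sid in flagged["scan_id"]:
        vol = np.asarray(getattr(volumes[index[sid]], "voxels", volumes[index[sid]]))
        fig, axes = plt.subplots(1, 3, figsize=(7, 2.4))
        centers = [s // 2 for s in vol.shape]
        for ax, sl in zip(axes, (vol[centers[0]], vol[:, centers[1]],
                                 vol[:, :, centers[2]])):
            ax.imshow(sl.T, cmap="gray", origin="lower")
            ax.axis("off")
        fig.suptitle(sid, fontsize=9)
        p = out / f"{sid}.png"
        fig.savefig(p, dpi=90, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)
    return paths


def run_qc(cohort: pd.DataFrame, volumes, config: QCConfig | None = None,
           group_col: str = "group", external_pass=None) -> QCReport:
    """Run all three detectors within each subgroup stratum independently.

    ``cohort`` needs scan_id and subgroup columns aligned with ``volumes``
    (list or array, one volume per row). Subgroups below
    ``config.min_subgroup_n`` are skipped with a warning. ``external_pass``
    optionally maps scan_id -> bool from an upstream screening tool; False
    entries are recorded as pre-flagged.
    """
    config = config or QCConfig()
    vols = [np.asarray(getattr(v, "voxels", v), dtype=float) for v in volumes]
    if len(vols) != len(cohort):
        raise ValueError("one volume per cohort row required")
    frames = []
    for group, sub in cohort.groupby(group_col, sort=True):
        idx = sub.index.to_numpy()
        ids = sub["scan_id"].tolist()
        gvols = [vols[cohort.index.get_loc(i)] for i in idx]
        if len(gvols) < config.min_subgroup_n:
            log.warning("subgroup %s has n=%d < %d; QC skipped",
                        group, len(gvols), config.min_subgroup_n)
            continue
        fi = intensity_outliers(gvols, ids, z_thresh=config.z_thresh,
                                extreme_z_thresh=config.extreme_z_thresh)
        fm = pca_mahalanobis_outliers(gvols, ids, config.variance_retained,
                                      config.chi2_quantile, config.max_components)
        ff = isoforest_outliers(gvols, ids, config.contamination, config.seed,
                                config.variance_retained, config.max_components)
        merged = fi.merge(fm, on="scan_id").merge(ff, on="scan_id")
        merged.insert(1, "subgroup", group)
        frames.append(merged)
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(columns=["scan_id", "subgroup", "flag_intensity",
                                      "flag_mahalanobis", "flag_isoforest"])
    for col in ("flag_intensity", "flag_mahalanobis", "flag_isoforest"):
        if col not in table:
            table[col] = pd.Series(dtype=bool)
    table["flag_external"] = False
    if external_pass:
        table["flag_external"] = table["scan_id"].map(
            lambda s: not external_pass.get(s, True))
    table["flagged"] = (table["flag_intensity"] | table["flag_mahalanobis"]
                        | table["flag_isoforest"] | table["flag_external"])
    thresholds = {
        "z_thresh": config.z_thresh,
        "variance_retained": config.variance_retained,
        "chi2_quantile": config.chi2_quantile,
        "contamination": config.contamination,
        "seed": config.seed,
    }
    return QCReport(table=table, thresholds=thresholds)
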