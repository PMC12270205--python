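"""Biomarker subgrouping, scan selection, and age-stratified data splits.

AD positivity is defined by the CSF p-tau181/Abeta42 ratio against the
0.021 threshold (ratio >= threshold is AD+); Lewy-body status by the SAA
readout (positive -> LB+, negative -> LB-, intermediate -> excluded).
Train/validation/test splits are stratified over discretized age bins
with a global largest-remainder allocation that reproduces exact 80/10/10
counts: train = round(0.8 N), validation = floor(0.1 N), test = remainder.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synth import AD_THRESHOLD

log = logging.getLogger(__name__)

SPLITS = ("train", "validation", "test")
DEFAULT_FRACTIONS = (0.8, 0.1, 0.1)


def classify_subgroup(ptau181: float, abeta42: float, saa: str,
                      threshold: float = AD_THRESHOLD) -> str:
    """Classify one record into an AD/LB subgroup or 'excluded'.

    Intermediate SAA readouts are excluded regardless of the ratio;
    missing biomarkers also exclude. The boundary ratio == threshold
    counts as AD+.
    """
    if saa == "intermediate":
        return "excluded"
    if saa not in ("positive", "negative"):
        raise ValueError(f"unknown SAA status {saa!r}")
    if ptau181 is None or abeta42 is None or np.isnan(ptau181) or np.isnan(abeta42):
        return "excluded"
    if abeta42 <= 0:
        raise ValueError("abeta42 must be positive")
    ad = "AD+" if ptau181 / abeta42 >= threshold else "AD-"
    lb = "LB+" if saa == "positive" else "LB-"
    return f"{ad}{lb}"


def classify_table(table: pd.DataFrame, threshold: float = AD_THRESHOLD) -> pd.Series:
    """Vectorized subgroup labels for a cohort table."""
    return table.apply(
        lambda r: classify_subgroup(r["ptau181"], r["abeta42"], r["saa"], threshold),
        axis=1)


def select_first_scan(scans: pd.DataFrame, subject_col: str = "subject_id",
                      date_col: str = "date", scan_col: str = "scan_id") -> pd.DataFrame:
    """Keep each subject's earliest scan; date ties break on scan id.

    ``date_col`` may hold dates, years, or visit indices - anything
    totally ordered. Missing dates raise.
    """
    if date_col not in scans.columns:
        raise ValueError(f"no {date_col!r} column and no visit order available")
    if scans[date_col].isna().any():
        raise ValueError("missing dates; cannot order scans")
    ordered = scans.sort_values([subject_col, date_col, scan_col], kind="mergesort")
    return ordered.groupby(subject_col, sort=False).head(1).reset_index(drop=True)


def pair_biomarker_window(table: pd.DataFrame, saa_date_col: str = "saa_date",
                          csf_date_col: str = "csf_date",
                          mri_date_col: str = "mri_date",
                          window_years: float = 1.0) -> pd.Series:
    """Real-data pairing filter: keep records whose CSF draw and MRI scan
    both fall within ``window_years`` of the SAA test date.

    Date columns hold decimal years (or anything subtractable). Returns a
    boolean mask; missing dates fail the filter.
    """
    saa = pd.to_numeric(table[saa_date_col], errors="coerce")
    csf = pd.to_numeric(table[csf_date_col], errors="coerce")
    mri = pd.to_numeric(table[mri_date_col], errors="coerce")
    ok = ((csf - saa).abs() <= window_years) & ((mri - saa).abs() <= window_years)
    return ok.fillna(False)


@dataclass
class SplitAssignment:
    labels: pd.Series            # per-record split label, index-aligned
    bin_edges: np.ndarray
    seed: int
    counts: dict = field(default_factory=dict)


def _global_targets(n: int, fractions) -> dict:
    """train = round(f0*N), validation = floor(f1*N), test = remainder."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    train = int(round(fractions[0] * n))
    val = int(np.floor(fractions[1] * n))
    test = n - train - val
    if min(train, val, test) < 0:
        raise ValueError("degenerate fractions for this N")
    return {"train": train, "validation": val, "test": test}


def _largest_remainder(bin_sizes: np.ndarray, total: int) -> np.ndarray:
    """Allocate ``total`` across bins proportionally by floor + largest remainder."""
    if bin_sizes.sum() == 0:
        return np.zeros_like(bin_sizes)
    ideal = bin_sizes * (total / bin_sizes.sum())
    base = np.floor(ideal).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(ideal - base), kind="stable")
    base[order[:rem]] += 1
    return base


def stratified_split(table: pd.DataFrame, fractions=DEFAULT_FRACTIONS,
                     bin_width: float = 5.0, seed: int = 42,
                     age_col: str = "CA") -> SplitAssignment:
    """Age-stratified train/validation/test split with exact global counts.

    Ages are discretized into ``bin_width``-year bins; within each bin the
    seeded shuffle assigns records, and per-bin quotas follow the
    largest-remainder rule against the exact global targets, so the split
    counts depend only on N. The assignment is invariant to input row
    order for a fixed seed (records are keyed by a stable sort before
    shuffling).
    """
    if table[age_col].isna().any():
        raise ValueError("every record needs an age")
    n = len(table)
    targets = _global_targets(n, fractions)
    ages = table[age_col].to_numpy(dtype=float)
    lo = np.floor(ages.min() / bin_width) * bin_width if n else 0.0
    hi = np.ceil((ages.max() + 1e-9) / bin_width) * bin_width if n else bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    idx_bins = np.clip(np.digitize(ages, edges) - 1, 0, max(len(edges) - 2, 0))

    # stable ordering: sort record positions within a bin by a stable key
    key = table["scan_id"].astype(str).to_numpy() if "scan_id" in table.columns \
        else table.index.astype(str).to_numpy()
    rng = np.random.default_rng(seed)
    labels = np.empty(n, dtype=object)

    bin_ids = np.unique(idx_bins) if n else np.array([], dtype=int)
    bin_sizes = np.array([(idx_bins == b).sum() for b in bin_ids])
    quota = {}
    remaining = bin_sizes.copy()
    for split in ("train", "validation"):
        alloc = _largest_remainder(bin_sizes, targets[split]) if len(bin_sizes) else []
        # never allocate more than remains in a bin; spill to other bins
        alloc = np.asarray(alloc, dtype=int)
        over = alloc - remaining
        if len(alloc) and (over > 0).any():
            spill = int(over[over > 0].sum())
            alloc = np.minimum(alloc, remaining)
            room = remaining - alloc
            order = np.argsort(-room, kind="stable")
            for b in order:
                if spill == 0:
                    break
                take = min(spill, room[b])
                alloc[b] += take
                spill -= take
            log.warning("bin quota spill occurred for split %s", split)
        quota[split] = alloc
        remaining = remaining - alloc
    quota["test"] = remaining

    for bi, b in enumerate(bin_ids):
        members = np.flatnonzero(idx_bins == b)
        members = members[np.argsort(key[members], kind="stable")]
        members = members[rng.permutation(len(members))]
        start = 0
        for split in SPLITS:
            q = int(quota[split][bi])
            labels[members[start:start + q]] = split
            start += q
    ser = pd.Series(labels, index=table.index, name="split")
    counts = {s: int((ser == s).sum()) for s in SPLITS}
    assert counts == targets, (counts, targets)
    return SplitAssignment(labels=ser, bin_edges=edges, seed=seed, counts=counts)


def balance_check(split: SplitAssignment, table: pd.DataFrame,
                  age_col: str = "CA", sex_col: str = "sex") -> dict:
    """One-way ANOVA of age across splits and chi-square of sex x split."""
    labels = split.labels
    groups = [table.loc[labels == s, age_col].to_numpy() for s in SPLITS
              if (labels == s).sum() > 0]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty splits")
    out = {}
    if all(len(g) >= 2 for g in groups):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, p = stats.f_oneway(*groups)
        if np.isnan(f):  # identical constant groups
            f, p = 0.0, 1.0
        out["age_F"], out["age_p"] = float(f), float(p)
    else:
        warnings.warn("a split has n<2; age ANOVA skipped")
        out["age_F"] = out["age_p"] = np.nan
    ct = pd.crosstab(table[sex_col], labels)
    if ct.shape[0] > 1 and ct.shape[1] > 1:
        chi2, p, _, _ = stats.chi2_contingency(ct)
        out["sex_chi2"], out["sex_p"] = float(chi2), float(p)
    else:
        out["sex_chi2"], out["sex_p"] = 0.0, 1.0
    return out
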