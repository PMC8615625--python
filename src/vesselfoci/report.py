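"""Variable transforms, per-group summaries and a permutation comparison.

The per-nucleus tables feed external inferential models (linear
mixed-effects on √cfoci and log nucleus area); this module applies those
transforms, aggregates per arm/tumor/category, and offers a seeded
difference-of-means permutation test as a lightweight convenience
comparison — it is not a substitute for the mixed model, which must
account for the tumor-level grouping.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["transform_metrics", "aggregate", "permutation_compare"]

#: Variables summarised per group, post-transform.
_SUMMARY_VARS = ["n_foci", "cfoci", "sqrt_cfoci", "area_um2", "log_area",
                 "median_mutual_distance_um"]


def transform_metrics(records: pd.DataFrame) -> pd.DataFrame:
    """Add ``sqrt_cfoci`` (√cfoci) and ``log_area`` (natural log, µm²).

    Variance-stabilising transforms for count-like cfoci and right-skewed
    nucleus areas.  Areas must be positive; cfoci may be NaN for
    non-enumerated nuclei and stays NaN through the transform.
    """
    df = records.copy()
    if (df["area_um2"] <= 0).any():
        raise ValueError("nucleus areas must be positive for the log transform")
    if (df["cfoci"].dropna() < 0).any():
        raise ValueError("cfoci must be non-negative")
    df["sqrt_cfoci"] = np.sqrt(df["cfoci"])
    df["log_area"] = np.log(df["area_um2"])
    df.attrs["log_base"] = "e"
    return df


def aggregate(records: pd.DataFrame,
              by: tuple[str, ...] = ("arm_id", "tumor_id", "category")) -> pd.DataFrame:
    """Group means/SDs of the transformed metrics, one row per group.

    Transforms are applied elementwise before averaging.  Rows are ordered
    lexicographically by the grouping keys; groups with no enumerated
    nucleus are omitted; the SD of a single observation is reported missing.
    """
    df = transform_metrics(records)
    df = df[df["cfoci"].notna()]
    out_rows = []
    for keys, grp in df.groupby(list(by), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        row = dict(zip(by, keys))
        row["n_nuclei"] = len(grp)
        for var in _SUMMARY_VARS:
            vals = grp[var].dropna().to_numpy(dtype=float)
            row[f"mean_{var}"] = vals.mean() if vals.size else np.nan
            row[f"sd_{var}"] = vals.std(ddof=1) if vals.size > 1 else np.nan
        out_rows.append(row)
    return pd.DataFrame(out_rows)


def permutation_compare(group_a, group_b, n_perm: int = 10000,
                        seed: int = 0) -> float:
    """Two-sided difference-of-means permutation p-value.

    p = (1 + #{permutations with |Δmean| ≥ observed}) / (n_perm + 1),
    the add-one estimator, which never returns 0 and is valid as a test.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    observed = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    n_a = a.size
    rng = np.random.default_rng(seed)
    count = 0
    total = pooled.sum()
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        mean_a = perm[:n_a].mean()
        mean_b = (total - perm[:n_a].sum()) / b.size
        if abs(mean_a - mean_b) >= observed - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)
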