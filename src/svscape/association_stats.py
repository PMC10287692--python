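"""Subtype vs clinical/molecular feature association testing.

Each subtype is compared one-vs-rest per feature: two-sided Welch's t-test
for continuous features, two-sided Fisher's exact test for binary/categorical
features. Samples can be excluded per feature (e.g. hypermutators treated as
outliers for mutation counts). P-values are reported raw, matching the
typical per-cell presentation of such tables; Benjamini-Hochberg adjustment
is available but off by default.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import DEFAULTS

FEATURE_KINDS = ("continuous", "categorical")


def test_feature(assignments: pd.Series, feature: pd.Series,
                 feature_kind: str, feature_name: str | None = None,
                 exclusions: Iterable[str] = (),
                 ) -> pd.DataFrame:
    """One-vs-rest association of every subtype with one feature.

    Parameters
    ----------
    assignments
        sample_id -> subtype label.
    feature
        sample_id -> value; continuous (float) or categorical. A categorical
        feature is tested per level as a 2x2 presence table (binary features
        are tested once).
    exclusions
        Samples dropped before testing (e.g. hypermutator outliers).

    Returns
    -------
    Long-format frame: subtype, feature, test, direction, p_value.
    """
    if feature_kind not in FEATURE_KINDS:
        raise ValueError(f"unknown feature_kind {feature_kind!r}")
    name = feature_name or (feature.name if feature.name is not None else "feature")
    keep = assignments.index.difference(pd.Index(list(exclusions)))
    keep = keep.intersection(feature.dropna().index)
    sub = assignments.loc[keep]
    val = feature.loc[keep]
    rows = []
    for subtype in sorted(sub.unique()):
        in_grp = sub == subtype
        if in_grp.sum() < 2 or (~in_grp).sum() < 2:
            continue
        if feature_kind == "continuous":
            a = val[in_grp].astype(float)
            b = val[~in_grp].astype(float)
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
                p = 1.0  # degenerate: no variance anywhere
            else:
                _, p = stats.ttest_ind(a, b, equal_var=False)
            direction = "increased" if a.mean() >= b.mean() else "decreased"
            rows.append((subtype, name, "welch_t", direction, float(p)))
        else:
            levels = sorted(val.unique())
            if len(levels) == 2:
                levels = levels[-1:]  # binary: one test on the higher level
            for level in levels:
                has = val == level
                table = [[int((in_grp & has).sum()), int((in_grp & ~has).sum())],
                         [int((~in_grp & has).sum()), int((~in_grp & ~has).sum())]]
                odds, p = stats.fisher_exact(table, alternative="two-sided")
                frac_in = table[0][0] / max(in_grp.sum(), 1)
                frac_out = table[1][0] / max((~in_grp).sum(), 1)
                direction = "increased" if frac_in >= frac_out else "decreased"
                label = name if len(levels) == 1 else f"{name}={level}"
                rows.append((subtype, label, "fisher_exact", direction, float(p)))
    return pd.DataFrame(rows, columns=["subtype", "feature", "test",
                                       "direction", "p_value"])


def test_features(assignments: pd.Series, features: pd.DataFrame,
                  kinds: Mapping[str, str],
                  exclusions: Mapping[str, Iterable[str]] | None = None,
                  ) -> pd.DataFrame:
    """Run :func:`test_feature` over the columns of a feature table."""
    parts = []
    for col, kind in kinds.items():
        excl = (exclusions or {}).get(col, ())
        parts.append(test_feature(assignments, features[col], kind,
                                  feature_name=col, exclusions=excl))
    if not parts:
        return pd.DataFrame(columns=["subtype", "feature", "test",
                                     "direction", "p_value"])
    return pd.concat(parts, ignore_index=True)


def summarize(results: pd.DataFrame, alpha: float | None = None,
              adjust: bool = False) -> pd.DataFrame:
    """Keep associations with p <= alpha (inclusive), arrow-annotated.

    ``adjust=True`` applies Benjamini-Hochberg first and filters on q.
    """
    alpha = DEFAULTS["assoc_alpha"] if alpha is None else alpha
    if len(results) == 0:
        return results.assign(arrow=pd.Series(dtype=str))
    out = results.copy()
    if adjust:
        _, q, _, _ = multipletests(out["p_value"], method="fdr_bh")
        out["q_value"] = q
        out = out[out["q_value"] <= alpha]
    else:
        out = out[out["p_value"] <= alpha]
    out = out.copy()
    out["arrow"] = np.where(out["direction"] == "increased", "up", "down")
    return out.reset_index(drop=True)
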