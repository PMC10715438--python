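"""Group statistics: Mann-Whitney U, Bonferroni, Pearson, ROC/AUC.

The comparison machinery mirrors how small imaging cohorts are analysed:
tumor-level values are compared between two arms with the two-sided
Mann-Whitney U-test, p-values are Bonferroni-corrected within an
explicitly declared family (never an implicit global one), and
discrimination of a binary outcome by a density is summarized as ROC/AUC,
with the AUC p-value taken from the exact U-test equivalence
AUC = U / (n₁·n₂).

Sidedness is two-sided throughout. An AUC below 0.5 is reported as-is
with an orientation flag rather than silently flipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve

ALPHA = 0.05


@dataclass
class ComparisonResult:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    U: float
    p_raw: float
    p_adjusted: float = np.nan
    family_size: int = 1

    @property
    def significant(self) -> bool:
        p = self.p_adjusted if np.isfinite(self.p_adjusted) else self.p_raw
        return bool(p <= ALPHA)


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    p_value: float
    n_pos: int
    n_neg: int
    #: True when the score runs the "wrong way" (AUC < 0.5).
    inverted: bool = False
    quality: str = field(init=False)

    def __post_init__(self) -> None:
        # conventional interpretation bands: >0.7 good, ≤0.5 uninformative
        if self.auc > 0.7:
            self.quality = "good (>0.7)"
        elif self.auc > 0.5:
            self.quality = "weak (0.5-0.7)"
        else:
            self.quality = "uninformative (<=0.5)"


def mann_whitney(values_a, values_b, group_a: str = "a", group_b: str = "b") -> ComparisonResult:
    """Two-sided Mann-Whitney U-test.

    U is the rank-sum statistic of sample a (midranks for ties). The p-value
    is exact (full enumeration of rank assignments) when n_a + n_b ≤ 12 and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections is used.
    """
    a = _clean(values_a, "values_a")
    b = _clean(values_b, "values_b")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = (len(a) + len(b)) <= 12
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return ComparisonResult(
        group_a=group_a,
        group_b=group_b,
        n_a=len(a),
        n_b=len(b),
        U=float(res.statistic),
        p_raw=float(res.pvalue),
    )


def bonferroni(p_values, family_size: int | None = None) -> np.ndarray:
    """p_adj = min(1, m·p). The family size m is explicit, never inferred
    beyond defaulting to the length of the input vector."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = family_size if family_size is not None else len(p)
    if m < 1:
        raise ValueError("family size must be >= 1")
    return np.minimum(1.0, m * p)


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-sided p (t-transform, n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson requires two equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson is undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def roc(scores, labels, positive_label) -> RocResult:
    """ROC curve over all unique score thresholds, AUC by trapezoid.

    The AUC p-value (against AUC = 0.5) comes from the Mann-Whitney test
    on positive vs negative scores, which is exact for the null that the
    score is exchangeable between classes.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == positive_label]
    neg = scores[labels != positive_label]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(labels == positive_label, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    cmp = mann_whitney(pos, neg)
    return RocResult(
        thresholds=thr,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        p_value=cmp.p_raw,
        n_pos=len(pos),
        n_neg=len(neg),
        inverted=auc < 0.5,
    )


# ----------------------------------------------------------------------
# contrast plans
# ----------------------------------------------------------------------

def run_comparisons(tumor_table: pd.DataFrame, plan: list[dict]) -> pd.DataFrame:
    """Execute a declared contrast plan against a tumor-level density table.

    ``plan`` is a list of named blocks; each block defines one Bonferroni
    family::

        {"name": "pv_vs_nonpv_untreated",
         "contrasts": [
             {"selector": "TAM", "compartment_a": "STROMA_PV",
              "compartment_b": "STROMA_NONPV", "where": {"treatment": "untreated"}},
             {"selector": "TAM", "group_by": "outcome",
              "arms": ["DF", "Mets"], "where": {"treatment": "NAC"}},
         ]}

    Two contrast forms exist: paired compartments within the same tumors
    (``compartment_a``/``compartment_b``), and two arms of a grouping
    variable within one compartment (``group_by``/``arms`` +
    ``compartment``). All tests are two-sided Mann-Whitney; within a block
    every raw p is multiplied by the block's contrast count (clipped at 1).
    """
    rows = []
    for block in plan:
        m = len(block["contrasts"])
        for spec in block["contrasts"]:
            sub = tumor_table[tumor_table["selector"] == spec["selector"]]
            for col, val in spec.get("where", {}).items():
                sub = sub[sub[col] == val]
            if "compartment_a" in spec:
                a = sub.loc[sub["compartment"] == spec["compartment_a"], "value"].dropna()
                b = sub.loc[sub["compartment"] == spec["compartment_b"], "value"].dropna()
                name_a, name_b = spec["compartment_a"], spec["compartment_b"]
            else:
                gb = spec["group_by"]
                arm_a, arm_b = spec["arms"]
                comp = spec.get("compartment")
                if comp is not None:
                    sub = sub[sub["compartment"] == comp]
                a = sub.loc[sub[gb] == arm_a, "value"].dropna()
                b = sub.loc[sub[gb] == arm_b, "value"].dropna()
                name_a, name_b = str(arm_a), str(arm_b)
            if len(a) == 0 or len(b) == 0:
                raise ValueError(
                    f"contrast {block['name']}/{spec['selector']}: an arm has no tumors"
                )
            res = mann_whitney(a, b, name_a, name_b)
            rows.append(
                {
                    "block": block["name"],
                    "selector": spec["selector"],
                    "compartment": spec.get("compartment")
                    or spec.get("compartment_a", ""),
                    "group_a": res.group_a,
                    "group_b": res.group_b,
                    "n_a": res.n_a,
                    "n_b": res.n_b,
                    "U": res.U,
                    "p_raw": res.p_raw,
                    "family_size": m,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = [
            float(bonferroni([p], m)[0]) for p, m in zip(out["p_raw"], out["family_size"])
        ]
        out["significant"] = out["p_adjusted"] <= ALPHA
    return out


def blind_labels(manifest_table: pd.DataFrame, rng: np.random.Generator) -> tuple[pd.DataFrame, dict]:
    """Blinded-analysis helper: replace group labels with opaque codes.

    Returns the recoded table and the unblinding key (code → true label),
    to be applied only after all comparisons are locked.
    """
    groups = sorted(manifest_table["group"].unique())
    codes = [f"G{i + 1}" for i in range(len(groups))]
    perm = rng.permutation(len(groups))
    mapping = {groups[perm[i]]: codes[i] for i in range(len(groups))}
    blinded = manifest_table.copy()
    blinded["group"] = blinded["group"].map(mapping)
    key = {v: k for k, v in mapping.items()}
    return blinded, key


def _clean(values, name: str) -> np.ndarray:
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    if len(v) == 0:
        raise ValueError(f"{name} is empty or all-NA")
    return v
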