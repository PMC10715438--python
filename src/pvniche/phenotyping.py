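"""Phenotype gating from boolean marker calls.

Each segmented cell carries a boolean call per marker. Gating maps those
booleans to a single exclusive phenotype by a fixed priority order
(first matching rule wins):

    ENDOTHELIAL  CD31+
    TAM          CD163+
    CD8_T        CD3+ CD8+
    TREG         CD3+ CD4+ FOXP3+
    CD4_T        CD3+ CD4+ FOXP3-
    CANCER       PanCK+
    OTHER        anything else

T cells additionally receive an activation state from the activation
marker PD-1 and the exhaustion marker LAG-3: PD-1− is naïve, PD-1+LAG-3−
active, PD-1+LAG-3+ exhausted. A LAG-3+PD-1− cell is classified naïve
(PD-1− dominates) and counted in a QC tally. TAMs carry their PD-L1 and
TIM-3 status as attributes so the four PD-L1±/TIM-3± TAM subsets partition
the TAM population.

The marker panel makes some co-positivity patterns ambiguous (e.g.
CD163+CD3+); the priority order resolves them deterministically and the
ambiguous patterns are tallied so the choice stays visible. Rules are data
(:class:`GatingConfig`), not code, so the panel can be re-gated without a
code change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

PHENOTYPES = ["TAM", "CD4_T", "CD8_T", "TREG", "CANCER", "ENDOTHELIAL", "OTHER"]
T_CELL_LABELS = ("CD4_T", "CD8_T")
ACTIVATION_STATES = ["NAIVE", "ACTIVE", "EXHAUSTED"]

#: Canonical marker column order for cell tables.
MARKERS = ["PanCK", "CD31", "CD3", "CD4", "CD8", "FOXP3", "PD1", "PDL1", "TIM3", "LAG3", "CD163"]


@dataclass
class GatingRule:
    label: str
    require_pos: list[str] = field(default_factory=list)
    require_neg: list[str] = field(default_factory=list)

    def matches(self, cells: pd.DataFrame) -> np.ndarray:
        ok = np.ones(len(cells), dtype=bool)
        for m in self.require_pos:
            ok &= cells[m].to_numpy(dtype=bool)
        for m in self.require_neg:
            ok &= ~cells[m].to_numpy(dtype=bool)
        return ok


@dataclass
class GatingConfig:
    """Ordered gating rules; the first matching rule assigns the label."""

    rules: list[GatingRule]
    fallback: str = "OTHER"

    @classmethod
    def default(cls) -> "GatingConfig":
        return cls(
            rules=[
                GatingRule("ENDOTHELIAL", ["CD31"]),
                GatingRule("TAM", ["CD163"]),
                GatingRule("CD8_T", ["CD3", "CD8"]),
                GatingRule("TREG", ["CD3", "CD4", "FOXP3"]),
                GatingRule("CD4_T", ["CD3", "CD4"], ["FOXP3"]),
                GatingRule("CANCER", ["PanCK"]),
            ]
        )

    @classmethod
    def from_file(cls, path) -> "GatingConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) if str(path).endswith((".yaml", ".yml")) else json.load(fh)
        rules = [
            GatingRule(r["label"], list(r.get("require_pos", [])), list(r.get("require_neg", [])))
            for r in raw["rules"]
        ]
        return cls(rules=rules, fallback=raw.get("fallback", "OTHER"))

    def to_dict(self) -> dict:
        return {
            "rules": [
                {"label": r.label, "require_pos": r.require_pos, "require_neg": r.require_neg}
                for r in self.rules
            ],
            "fallback": self.fallback,
        }

    def markers_used(self) -> list[str]:
        seen: list[str] = []
        for r in self.rules:
            for m in r.require_pos + r.require_neg:
                if m not in seen:
                    seen.append(m)
        return seen


def phenotype_table(
    cells: pd.DataFrame, rules: GatingConfig | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Gate every cell; returns the labeled table and a QC summary.

    The returned frame is ``cells`` with four added columns: ``label``,
    ``activation`` (NA for non-T cells), ``tam_pdl1`` and ``tam_tim3``
    (NA for non-TAMs). The QC summary counts marker patterns the priority
    order had to resolve: CD3+CD4+CD8+ double positives, CD8+FOXP3+
    cells, and LAG-3+PD-1− T cells.
    """
    rules = rules or GatingConfig.default()
    out = cells.copy()
    n = len(cells)
    label = np.full(n, rules.fallback, dtype=object)
    unassigned = np.ones(n, dtype=bool)
    for rule in rules.rules:
        hit = rule.matches(cells) & unassigned
        label[hit] = rule.label
        unassigned &= ~hit
    out["label"] = label

    is_t = np.isin(label, T_CELL_LABELS)
    pd1 = _col(cells, "PD1", n)
    lag3 = _col(cells, "LAG3", n)
    activation = np.full(n, pd.NA, dtype=object)
    activation[is_t & ~pd1] = "NAIVE"
    activation[is_t & pd1 & ~lag3] = "ACTIVE"
    activation[is_t & pd1 & lag3] = "EXHAUSTED"
    out["activation"] = activation

    is_tam = label == "TAM"
    pdl1 = _col(cells, "PDL1", n)
    tim3 = _col(cells, "TIM3", n)
    out["tam_pdl1"] = pd.array(np.where(is_tam, pdl1, None), dtype="boolean")
    out["tam_tim3"] = pd.array(np.where(is_tam, tim3, None), dtype="boolean")

    cd3 = _col(cells, "CD3", n)
    cd4 = _col(cells, "CD4", n)
    cd8 = _col(cells, "CD8", n)
    foxp3 = _col(cells, "FOXP3", n)
    qc = {
        "cd4_cd8_double_positive": int(np.count_nonzero(cd3 & cd4 & cd8)),
        "cd8_foxp3_positive": int(np.count_nonzero(is_t & cd8 & foxp3)),
        "lag3_single_positive_t": int(np.count_nonzero(is_t & lag3 & ~pd1)),
    }
    return out, qc


def gate_cell(cell: pd.Series | dict, rules: GatingConfig | None = None) -> dict:
    """Gate a single cell; returns label / activation / tam_pdl1 / tam_tim3."""
    df = pd.DataFrame([dict(cell)])
    labeled, _ = phenotype_table(df, rules)
    row = labeled.iloc[0]
    return {
        "label": row["label"],
        "activation": row["activation"] if not pd.isna(row["activation"]) else None,
        "tam_pdl1": None if pd.isna(row["tam_pdl1"]) else bool(row["tam_pdl1"]),
        "tam_tim3": None if pd.isna(row["tam_tim3"]) else bool(row["tam_tim3"]),
    }


def _col(cells: pd.DataFrame, name: str, n: int) -> np.ndarray:
    if name in cells.columns:
        return cells[name].to_numpy(dtype=bool)
    return np.zeros(n, dtype=bool)


# ----------------------------------------------------------------------
# phenotype selectors (shared mini-language)
# ----------------------------------------------------------------------

def parse_selector(expr: str):
    """Compile a selector like ``"label==TAM & tam_tim3 & !tam_pdl1"``.

    Terms are joined with ``&``. Each term is either ``column==value``,
    ``!column`` / ``!PHENOTYPE``, a bare boolean column, or a bare
    phenotype label (shorthand for ``label==X``). Values ``true``/``false``
    are booleans; anything else is a string literal. Returns a function
    mapping a labeled cell table to a boolean mask.
    """
    terms = [t.strip() for t in expr.split("&") if t.strip()]
    if not terms:
        raise ValueError(f"empty selector: {expr!r}")

    def parse_term(term: str):
        negate = term.startswith("!")
        if negate:
            term = term[1:].strip()
        if "==" in term:
            col, _, val = term.partition("==")
            col, val = col.strip(), val.strip()
            value: object
            if val.lower() in ("true", "false"):
                value = val.lower() == "true"
            else:
                value = val
        elif term in PHENOTYPES:
            col, value = "label", term
        else:
            col, value = term, True
        return col, value, negate

    parsed = [parse_term(t) for t in terms]

    def apply(df: pd.DataFrame) -> pd.Series:
        mask = pd.Series(True, index=df.index)
        for col, value, negate in parsed:
            if col not in df.columns:
                raise KeyError(f"selector references unknown column {col!r}")
            m = df[col] == value
            m = m.fillna(False) if hasattr(m, "fillna") else m
            mask &= ~m if negate else m
        return mask.astype(bool)

    apply.expression = expr  # type: ignore[attr-defined]
    return apply


def subset_proportion(
    labeled: pd.DataFrame,
    numerator: str,
    denominator: str,
    strata: list[str] | None = None,
) -> pd.DataFrame:
    """%-of-parent proportions, e.g. the fraction of TAMs that are TIM-3+.

    Computes numerator-count / denominator-count within each stratum
    (combination of the ``strata`` columns). The numerator is evaluated
    within the denominator population. Empty denominators yield NA, not an
    error.
    """
    num = parse_selector(numerator)
    den = parse_selector(denominator)
    in_den = den(labeled)
    in_num = num(labeled) & in_den
    work = pd.DataFrame({"_num": in_num, "_den": in_den})
    if strata:
        for c in strata:
            work[c] = labeled[c]
        g = work.groupby(strata, observed=True)[["_num", "_den"]].sum()
    else:
        g = work[["_num", "_den"]].sum().to_frame().T
    g = g.rename(columns={"_num": "n_numerator", "_den": "n_denominator"})
    g["proportion"] = np.where(
        g["n_denominator"] > 0, g["n_numerator"] / g["n_denominator"], np.nan
    )
    return g.reset_index()
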