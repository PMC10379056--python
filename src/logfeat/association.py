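"""Post-hoc structure analysis of mixed feature tables.

Three tools: factor analysis of mixed data (FAMD) — a PCA-like
ordination treating continuous columns as standardized variables and
categorical columns as weighted indicator blocks; a variable-by-
variable association matrix dispatching on types (Pearson r for
numeric pairs, the correlation ratio for categorical-numeric, and
Cramér's V for categorical pairs); and a greedy best-first
association-rule search ("hotspot") that grows conjunctive condition
paths toward high confidence for a target class subject to minimum
support.

FAMD weighting: a continuous column standardized to unit variance
contributes inertia 1; a categorical level's centered indicator
divided by the square root of its frequency contributes 1 - p, so a
variable with L levels contributes L - 1 and the total inertia is
(#continuous) + sum(L - 1).  On an all-continuous table FAMD reduces
exactly to PCA of the correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FAMDResult",
    "famd",
    "cramers_v",
    "correlation_ratio",
    "association_matrix",
    "HotspotRule",
    "hotspot_rules",
]


@dataclass
class FAMDResult:
    eigenvalues: np.ndarray  # non-increasing, >= 0
    explained_inertia: np.ndarray  # eigenvalues / total inertia
    total_inertia: float
    row_coords: pd.DataFrame  # n x n_dims
    column_coords: pd.DataFrame  # one row per continuous var / categorical level
    contrib: pd.DataFrame  # % contribution per column per dimension (sums to 100)
    cos2: pd.DataFrame  # quality of representation per column per dimension
    dropped: list = field(default_factory=list)


def _famd_design(df: pd.DataFrame):
    """Build the weighted, centered FAMD design matrix."""
    n = len(df)
    blocks, names, dropped = [], [], []
    for col in df.columns:
        s = df[col]
        if pd.api.types.is_numeric_dtype(s):
            x = s.to_numpy(dtype=float)
            sd = x.std(ddof=0)
            if sd == 0:
                dropped.append(col)
                continue
            blocks.append(((x - x.mean()) / sd)[:, None])
            names.append(col)
        else:
            dummies = pd.get_dummies(s.astype(str), prefix=col, prefix_sep="=")
            if dummies.shape[1] < 2:
                dropped.append(col)
                continue
            z = dummies.to_numpy(dtype=float)
            p = z.mean(axis=0)
            blocks.append((z - p) / np.sqrt(p))
            names.extend(dummies.columns)
    if not blocks:
        raise ValueError("no non-constant variables left for FAMD")
    return np.hstack(blocks), names, dropped


def famd(df: pd.DataFrame, n_dims: int | None = None) -> FAMDResult:
    """Factor analysis of mixed data.

    Continuous variables are standardized; categorical variables enter
    as centered indicator columns weighted by 1/sqrt(level frequency).
    Constant variables are dropped with a record in ``dropped``.

    Identities: eigenvalues sum to the total inertia; per-dimension
    variable contributions sum to 100%.
    """
    if df.shape[1] < 2:
        raise ValueError("FAMD needs at least two variables")
    M, names, dropped = _famd_design(df)
    n = len(df)
    U, svals, Vt = np.linalg.svd(M / np.sqrt(n), full_matrices=False)
    eig = svals**2
    keep = n_dims if n_dims is not None else int((eig > 1e-12).sum())
    keep = max(1, min(keep, len(eig)))
    dims = [f"dim_{i + 1}" for i in range(keep)]

    total_inertia = float(eig.sum())
    row_coords = pd.DataFrame(
        (U[:, :keep] * svals[:keep]) * np.sqrt(n), index=df.index, columns=dims
    )
    # column principal coordinates: loading * sqrt(eigenvalue)
    load = Vt.T[:, :keep]
    col_coords = pd.DataFrame(
        load * svals[:keep], index=names, columns=dims
    )
    contrib = pd.DataFrame(
        100.0 * load**2, index=names, columns=dims
    )
    col_inertia = (M**2).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos2 = pd.DataFrame(
            (load * svals[:keep]) ** 2 / col_inertia[:, None],
            index=names,
            columns=dims,
        )
    return FAMDResult(
        eigenvalues=eig,
        explained_inertia=eig / total_inertia,
        total_inertia=total_inertia,
        row_coords=row_coords,
        column_coords=col_coords,
        contrib=contrib,
        cos2=cos2,
        dropped=dropped,
    )


def cramers_v(x: Sequence, y: Sequence) -> float:
    """Cramér's V between two categorical variables (no bias correction)."""
    table = pd.crosstab(pd.Series(x), pd.Series(y))
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 0.0
    chi2 = stats.chi2_contingency(table, correction=False)[0]
    n = table.to_numpy().sum()
    k = min(table.shape) - 1
    return float(np.sqrt(chi2 / (n * k)))


def correlation_ratio(categories: Sequence, values: Sequence) -> float:
    """Correlation ratio eta: how much of a numeric variable's variance
    the categorical variable explains (oriented categorical -> numeric)."""
    df = pd.DataFrame({"c": pd.Series(categories), "v": pd.Series(values, dtype=float)})
    overall = df["v"].to_numpy()
    ss_total = ((overall - overall.mean()) ** 2).sum()
    if ss_total == 0:
        return 0.0
    ss_between = sum(
        len(g) * (g.mean() - overall.mean()) ** 2
        for _, g in df.groupby("c", observed=True)["v"]
    )
    return float(np.sqrt(ss_between / ss_total))


def association_matrix(
    df: pd.DataFrame, threshold: float | None = None
) -> pd.DataFrame:
    """Mixed-type association matrix.

    Pearson r for numeric pairs (in [-1, 1]), Cramér's V for
    categorical pairs and the correlation ratio for mixed pairs (both
    in [0, 1]; the mixed entry is oriented categorical-explains-
    numeric and written symmetrically).  Diagonal is 1.  With
    ``threshold`` set, a boolean screen |value| > threshold is also
    attached as ``.attrs["screen"]``.
    """
    cols = list(df.columns)
    for c in cols:
        if df[c].isna().all():
            raise ValueError(f"column {c!r} is entirely missing")
    numeric = {c for c in cols if pd.api.types.is_numeric_dtype(df[c])}
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            if a in numeric and b in numeric:
                v = float(df[a].corr(df[b]))
            elif a not in numeric and b not in numeric:
                v = cramers_v(df[a], df[b])
            else:
                cat, num = (a, b) if a not in numeric else (b, a)
                v = correlation_ratio(df[cat], df[num])
            out.loc[a, b] = out.loc[b, a] = v
    if threshold is not None:
        out.attrs["screen"] = out.abs() > threshold
    return out


@dataclass
class HotspotRule:
    conditions: tuple[tuple[str, str], ...]  # ((variable, level), ...)
    support: int
    confidence: float

    def describe(self) -> str:
        cond = " AND ".join(f"{v}={l}" for v, l in self.conditions) or "(root)"
        return f"{cond}  [n={self.support}, conf={self.confidence:.3f}]"


def hotspot_rules(
    df: pd.DataFrame,
    class_col: str,
    target_class: str,
    min_support: float = 0.3,
    max_depth: int = 3,
    branching: int = 3,
) -> list[HotspotRule]:
    """Greedy best-first search for conjunctive rules predicting a class.

    Starting from the root (all rows), each node tries every
    ``variable = level`` extension; the top ``branching`` extensions
    by target-class confidence that keep support at or above
    ``min_support`` (a fraction of the target-class mass) and strictly
    improve confidence are expanded, down to ``max_depth`` conditions.
    Returns all accepted rules including the root, depth-first.
    """
    if not 0 < min_support <= 1:
        raise ValueError("min_support must be in (0, 1]")
    y = df[class_col].astype(str)
    target_mass = int((y == target_class).sum())
    if target_mass == 0:
        raise ValueError(f"target class {target_class!r} absent")
    min_count = max(1, int(np.ceil(min_support * target_mass)))
    feature_cols = [c for c in df.columns if c != class_col]

    root_mask = np.ones(len(df), dtype=bool)
    root_conf = float((y == target_class).mean())
    rules: list[HotspotRule] = []
    if (y[root_mask] == target_class).sum() < min_count:
        return rules  # target mass below support floor: empty set
    root = HotspotRule(conditions=(), support=len(df), confidence=root_conf)
    rules.append(root)

    def expand(mask: np.ndarray, conditions, confidence, depth):
        if depth >= max_depth:
            return
        used = {v for v, _ in conditions}
        candidates = []
        for c in feature_cols:
            if c in used:
                continue
            col = df[c].astype(str)
            for level in sorted(col[mask].unique()):
                m2 = mask & (col == level).to_numpy()
                hits = int((y[m2] == target_class).sum())
                if hits < min_count:
                    continue
                conf = hits / int(m2.sum())
                if conf > confidence:
                    candidates.append((conf, c, level, m2))
        candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
        for conf, c, level, m2 in candidates[:branching]:
            rule = HotspotRule(
                conditions=conditions + ((c, level),),
                support=int(m2.sum()),
                confidence=conf,
            )
            rules.append(rule)
            expand(m2, rule.conditions, conf, depth + 1)

    expand(root_mask, (), root_conf, 0)
    return rules
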