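"""Pilot-phase miRNA target screen.

The screen crosses two evidence sources: (1) in-silico miRNA-target
predictions, read as one-symbol-per-line list files (one per database) and
intersected with a configurable minimum number of supporting databases; and
(2) a two-group differential-expression test on a log-expression matrix
(relapse vs matched control).  A predicted target passes the screen when it is
*down*-regulated in the relapse group at a deliberately permissive two-sided
p < alpha (default 0.2) — significance is tested two-sided and the
down-regulation direction is imposed afterwards as a filter.  No
multiple-testing correction is applied: the permissive alpha is paired with
the external database stringency, though a Benjamini–Hochberg column is
emitted for information.

Two test flavours are provided: a per-gene Welch t (default) and a moderated
t that shrinks per-gene variances toward a pooled inverse-gamma prior fitted
by moment matching — an empirical-Bayes scheme in the LIMMA family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "TargetListSet",
    "ExpressionMatrix",
    "read_target_list",
    "read_expression_tsv",
    "read_groups_csv",
    "intersect_targets",
    "de_screen",
]

RELAPSE = "relapse"
CONTROL = "control"


@dataclass(frozen=True)
class TargetListSet:
    """One database's predicted target genes, uppercased and deduplicated."""

    database_name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        for g in self.genes:
            if not g or any(ch.isspace() for ch in g):
                raise ValueError(f"{self.database_name}: bad gene symbol {g!r}")


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with a relapse/control sample annotation."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    group: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(self.group) != len(self.samples):
            raise ValueError("group annotation length mismatch")
        bad = set(self.group) - {RELAPSE, CONTROL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for label in (RELAPSE, CONTROL):
            if self.group.count(label) < 2:
                raise ValueError(f"group '{label}' needs >= 2 samples")

    def group_mask(self, label: str) -> np.ndarray:
        return np.array([g == label for g in self.group])


def read_target_list(path: str | Path, database_name: str) -> TargetListSet:
    """Read a plain-text target list (one symbol per line, '#' comments allowed)."""
    path = Path(path)
    genes: set[str] = set()
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.add(line.upper())
    if not genes:
        raise ValueError(f"target list {path} contains no gene symbols")
    return TargetListSet(database_name=database_name, genes=frozenset(genes))


def read_expression_tsv(expr_path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    """Read a genes-in-rows TSV (first column = symbol) plus a sample_id,group CSV."""
    df = pd.read_csv(expr_path, sep="\t", index_col=0)
    group_map = read_groups_csv(groups_path)
    missing = [s for s in df.columns if s not in group_map]
    if missing:
        raise ValueError(f"samples without group annotation: {missing}")
    return ExpressionMatrix(
        genes=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
        group=[group_map[s] for s in df.columns],
    )


def read_groups_csv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    if not {"sample_id", "group"} <= set(df.columns):
        raise ValueError("groups CSV needs columns sample_id, group")
    return dict(zip(df["sample_id"].str.strip(), df["group"].str.strip().str.lower()))


def intersect_targets(
    lists: Sequence[TargetListSet], min_databases: int = 1
) -> tuple[set[str], dict[str, int]]:
    """Genes predicted by at least ``min_databases`` of the supplied lists.

    Returns the selected gene set and, for every gene seen anywhere, the
    number of supporting databases.  ``min_databases=1`` is the union pool;
    higher values demand multi-database support.
    """
    if not lists:
        raise ValueError("need at least one target list")
    if not 1 <= min_databases <= len(lists):
        raise ValueError("min_databases must be between 1 and the number of lists")
    counts: dict[str, int] = {}
    for tl in lists:
        for g in tl.genes:
            counts[g] = counts.get(g, 0) + 1
    selected = {g for g, c in counts.items() if c >= min_databases}
    return selected, counts


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-row Welch t and two-sided p (rows = genes)."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = np.where(np.isfinite(t), 2 * stats.t.sf(np.abs(t), df), 1.0)
    # zero variance in both groups: equal means -> no evidence (p = 1);
    # different means -> infinitely strong evidence under the model (p = 0)
    degenerate = se2 == 0
    t = np.where(degenerate, np.where(ma == mb, 0.0, np.copysign(np.inf, ma - mb)), t)
    p = np.where(degenerate, np.where(ma == mb, 1.0, 0.0), p)
    return t, p


def _moderated(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical-Bayes moderated t with pooled-variance shrinkage.

    Per-gene pooled variances s_g^2 (residual df = na+nb-2) are shrunk toward
    a scaled inverse-chi-square prior (s0^2, d0) fitted to the observed
    variance distribution by moment matching on log s_g^2, and the t statistic
    uses the posterior variance with na+nb-2+d0 degrees of freedom.
    """
    na, nb = a.shape[1], b.shape[1]
    df_resid = na + nb - 2
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    s2 = ((a.var(axis=1, ddof=1) * (na - 1)) + (b.var(axis=1, ddof=1) * (nb - 1))) / df_resid

    # moment-match prior (d0, s0^2) on z = log s^2: if s^2 ~ s0^2 * F(df, d0)
    # then var(z) = trigamma(df/2) + trigamma(d0/2) and
    # E[z] = log s0^2 + digamma(df/2) - digamma(d0/2) - log(df/d0)
    pos = s2 > 0
    z = np.log(s2[pos])
    excess = max(z.var(ddof=1) - _trigamma(df_resid / 2), 1e-8)
    d0 = 2 * _inv_trigamma(excess)
    s0_sq = math.exp(
        z.mean() - _digamma(df_resid / 2) + _digamma(d0 / 2) + math.log(df_resid / d0)
    )

    s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
    se = np.sqrt(s2_post * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / se
    df_total = df_resid + d0
    p = np.where(np.isfinite(t), 2 * stats.t.sf(np.abs(t), df_total), 1.0)
    degenerate = se == 0
    t = np.where(degenerate, np.where(ma == mb, 0.0, np.copysign(np.inf, ma - mb)), t)
    p = np.where(degenerate, np.where(ma == mb, 1.0, 0.0), p)
    return t, p


def _digamma(x: float) -> float:
    return float(special.psi(x))


def _trigamma(x: float) -> float:
    return float(special.polygamma(1, x))


def _inv_trigamma(y: float) -> float:
    """Invert trigamma by Newton iteration (y > 0)."""
    x = 0.5 + 1.0 / y  # standard starting value
    for _ in range(50):
        step = (float(special.polygamma(1, x)) - y) / float(special.polygamma(2, x))
        x -= step
        if x <= 0:
            x = 1e-6
        if abs(step) < 1e-10:
            break
    return x


def de_screen(
    expr: ExpressionMatrix,
    targets: Iterable[str],
    alpha: float = 0.2,
    method: str = "welch",
) -> pd.DataFrame:
    """Relapse-vs-control screen over all genes, flagging down-regulated targets.

    Parameters
    ----------
    expr
        Log-expression matrix with group annotation.
    targets
        Predicted target symbols (from :func:`intersect_targets`).
    alpha
        Permissive screening threshold on the two-sided p-value (default 0.2).
    method
        ``"welch"`` (per-gene Welch t) or ``"moderated"`` (empirical-Bayes
        variance shrinkage).

    Returns
    -------
    pandas.DataFrame
        One row per gene with columns ``gene, mean_relapse, mean_control,
        log_fc, t_stat, p_value, p_bh, predicted_target,
        down_in_relapse_pass``, sorted by p-value ascending with alphabetical
        tie-break.  ``down_in_relapse_pass`` is true iff the gene is a
        predicted target with ``log_fc < 0`` and ``p_value < alpha``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    target_set = {t.upper() for t in targets}
    rel = expr.values[:, expr.group_mask(RELAPSE)]
    ctl = expr.values[:, expr.group_mask(CONTROL)]
    if method == "welch":
        t, p = _welch(rel, ctl)
    elif method == "moderated":
        t, p = _moderated(rel, ctl)
    else:
        raise ValueError(f"unknown method {method!r}")

    mean_rel = rel.mean(axis=1)
    mean_ctl = ctl.mean(axis=1)
    log_fc = mean_rel - mean_ctl
    genes_upper = np.array([g.upper() for g in expr.genes])
    predicted = np.isin(genes_upper, sorted(target_set))
    out = pd.DataFrame(
        {
            "gene": expr.genes,
            "mean_relapse": mean_rel,
            "mean_control": mean_ctl,
            "log_fc": log_fc,
            "t_stat": t,
            "p_value": p,
            "p_bh": _benjamini_hochberg(p),
            "predicted_target": predicted,
            "down_in_relapse_pass": predicted & (log_fc < 0) & (p < alpha),
        }
    )
    return out.sort_values(["p_value", "gene"], kind="mergesort").reset_index(drop=True)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (informational only; the screen does not gate on them)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    adj[order] = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.clip(adj, 0, 1)
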