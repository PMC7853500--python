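"""Group statistics on per-subject, per-condition parameter estimates.

The inversion yields, for every subject, condition-specific values of the
free connection gains and receptor time constants (the condition effects act
multiplicatively in log space).  The group question — does condition change
the laminar parameters? — is tested with a repeated-measures MANOVA on
within-subject difference scores (Wilks' lambda), followed by per-parameter
repeated-measures ANOVAs with Benjamini-Hochberg FDR correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .model import CHANNELS, ModelSpec
from .observation import CONDITION_LABELS, ConditionDesign

__all__ = [
    "ConditionParameterTable",
    "condition_parameters",
    "build_parameter_table",
    "rm_manova",
    "univariate_followups",
]


@dataclass
class ConditionParameterTable:
    """subject x condition x parameter array of condition-specific values."""

    values: np.ndarray
    parameter_labels: tuple
    condition_labels: tuple = CONDITION_LABELS
    subject_ids: tuple | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (n_subjects, n_conditions, n_parameters)")
        if self.values.shape[1] != 3:
            raise ValueError("exactly 3 conditions expected (pre, early_post, late_post)")
        if self.values.shape[2] != len(self.parameter_labels):
            raise ValueError("parameter_labels must match values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("missing or non-finite entries are not allowed")


def _baseline_value(spec: ModelSpec, name: str) -> float:
    """Default value of a free quantity: edge coupling gamma, or decay tau (ms)."""
    tag, _, quantity = name.partition(":")
    if tag == "g":
        src, tgt = quantity.split("->")
        kind = "GABA_A" if src in ("si", "di", "rt") else "AMPA"
        g = spec.gains[CHANNELS.index(kind), spec.index(tgt), spec.index(src)]
        return float(g / spec.receptor_mix[kind])
    if tag == "d":
        return float(1.0 / spec.kappa[CHANNELS.index(quantity)])
    raise ValueError(f"unknown quantity {name!r}")


def condition_parameters(posterior, dsgn: ConditionDesign, spec: ModelSpec,
                         parameters: tuple | None = None) -> np.ndarray:
    """Condition-specific parameter values for one subject, (3, n_parameters).

    Gains are reported as coupling strengths, decays as time constants (ms,
    the reciprocal of the modulated rate): values a clinician would plot per
    condition, obtained from exp(theta + sum_k beta X[k, c]) times the
    default.
    """
    if posterior.design and posterior.design != dsgn.name:
        raise ValueError(
            f"posterior was fitted under design {posterior.design!r}, not {dsgn.name!r}")
    pv = posterior.parameter_vector(spec, dsgn)
    parameters = tuple(parameters) if parameters is not None else pv.names
    out = np.empty((dsgn.n_conditions, len(parameters)))
    for c in range(dsgn.n_conditions):
        scale = np.exp(pv.theta + dsgn.X[:, c] @ pv.beta)
        for p, name in enumerate(parameters):
            q = pv.names.index(name)
            base = _baseline_value(spec, name)
            # decay rates scale by exp(.); time constants by exp(-.)
            s = scale[q] if name.startswith("g:") else 1.0 / scale[q]
            out[c, p] = base * s
    return out


def build_parameter_table(posteriors, dsgn: ConditionDesign, spec: ModelSpec,
                          parameters: tuple | None = None,
                          subject_ids=None) -> ConditionParameterTable:
    """Stack per-subject condition parameters into a group table."""
    rows = [condition_parameters(p, dsgn, spec, parameters) for p in posteriors]
    if parameters is None:
        from .observation import free_quantities
        parameters = free_quantities(spec)
    return ConditionParameterTable(
        values=np.stack(rows), parameter_labels=tuple(parameters),
        subject_ids=tuple(subject_ids) if subject_ids is not None else None,
    )


def _difference_scores(values: np.ndarray) -> np.ndarray:
    """Within-subject contrasts vs pre-tetanus: (n, 2p)."""
    d = values[:, 1:, :] - values[:, :1, :]
    return d.reshape(values.shape[0], -1)


def rm_manova(table: ConditionParameterTable):
    """Repeated-measures MANOVA for the condition effect.

    The multivariate test is applied to the within-subject difference scores
    (each parameter's early-minus-pre and late-minus-pre change), i.e. a
    one-sample test of zero mean change.  Wilks' lambda is det(E)/det(E+H),
    evaluated through the eigenvalues of E^-1 H, with Rao's F transformation
    (exact for a one-sample hypothesis).  Returns (lambda, F, (df1, df2), p).
    """
    Y = _difference_scores(table.values)
    n, q = Y.shape
    if n <= q:
        raise ValueError(
            f"{n} subjects cannot support {q} difference variables "
            f"({len(table.parameter_labels)} parameters x 2 contrasts); "
            "subset the parameters")
    ybar = Y.mean(axis=0)
    Yc = Y - ybar
    E = Yc.T @ Yc
    H = n * np.outer(ybar, ybar)
    if np.linalg.matrix_rank(E) < q:
        sd = Yc.std(axis=0)
        flat = [table.parameter_labels[i % len(table.parameter_labels)]
                for i in np.where(sd <= 1e-12 * max(sd.max(), 1.0))[0]]
        detail = f"zero-variance parameters: {sorted(set(flat))}" if flat else \
            "perfectly collinear parameter contrasts"
        raise ValueError(f"singular within-subject covariance; {detail}")
    eig = np.linalg.eigvals(np.linalg.solve(E, H)).real
    lam = float(np.prod(1.0 / (1.0 + eig)))
    df1, df2 = q, n - q
    f_stat = (df2 / df1) * (1.0 - lam) / lam if lam > 0 else np.inf
    p = float(sps.f.sf(f_stat, df1, df2)) if np.isfinite(f_stat) else 0.0
    if np.allclose(H, 0):
        lam, f_stat, p = 1.0, 0.0, 1.0
    return lam, float(f_stat), (df1, df2), p


def _rm_anova_one(values: np.ndarray):
    """One-way repeated-measures ANOVA (pingouin) for a single parameter (n, c)."""
    import pingouin as pg

    n, c = values.shape
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), c),
        "condition": np.tile(np.arange(c), n),
        "value": values.ravel(),
    })
    try:
        aov = pg.rm_anova(data=long, dv="value", within="condition",
                          subject="subject", correction=True)
    except ZeroDivisionError:
        # sphericity correction undefined for very small cohorts
        aov = pg.rm_anova(data=long, dv="value", within="condition",
                          subject="subject", correction=False)
    row = aov.iloc[0]
    p_gg = float(row["p_GG_corr"]) if "p_GG_corr" in aov.columns else float(row["p_unc"])
    eps = float(row["eps"]) if "eps" in aov.columns else 1.0
    return float(row["F"]), float(row["p_unc"]), p_gg, eps


def _hotelling_p(values: np.ndarray) -> float:
    """Multivariate (Hotelling) p for one parameter's condition differences."""
    d = values[:, 1:] - values[:, :1]
    n, q = d.shape
    if n <= q:
        return float("nan")
    dbar = d.mean(axis=0)
    S = np.cov(d.T, bias=False)
    try:
        t2 = n * dbar @ np.linalg.solve(S, dbar)
    except np.linalg.LinAlgError:
        return float("nan")
    f_stat = (n - q) / (q * (n - 1)) * t2
    return float(sps.f.sf(f_stat, q, n - q))


def univariate_followups(table: ConditionParameterTable, q: float = 0.05,
                         use_gg: bool = True) -> pd.DataFrame:
    """Per-parameter repeated-measures ANOVAs with BH-FDR correction.

    Returns a tidy frame with the F statistic, uncorrected,
    Greenhouse-Geisser-corrected and multivariate p-values, BH-adjusted p
    (over the non-degenerate parameters, on the GG-corrected p by default),
    the rejection flag at level ``q`` and the direction of change
    (sign of mean post-tetanus value minus pre-tetanus value).
    """
    records = []
    for p_idx, label in enumerate(table.parameter_labels):
        vals = table.values[:, :, p_idx]
        if np.ptp(vals) <= 1e-300 or np.allclose(vals.std(axis=0), 0):
            records.append(dict(parameter=label, F=np.nan, p_unc=np.nan,
                                p_gg=np.nan, p_multivariate=np.nan, eps=np.nan,
                                direction=0, excluded=True))
            continue
        if np.allclose(vals - vals[:, :1], 0):
            # no within-subject condition differences at all
            records.append(dict(parameter=label, F=0.0, p_unc=1.0, p_gg=1.0,
                                p_multivariate=1.0, eps=1.0, direction=0,
                                excluded=False))
            continue
        f_stat, p_unc, p_gg, eps = _rm_anova_one(vals)
        direction = int(np.sign(vals[:, 1:].mean() - vals[:, 0].mean()))
        records.append(dict(parameter=label, F=f_stat, p_unc=p_unc, p_gg=p_gg,
                            p_multivariate=_hotelling_p(vals), eps=eps,
                            direction=direction, excluded=False))
    df = pd.DataFrame.from_records(records)
    ok = ~df["excluded"]
    pcol = "p_gg" if use_gg else "p_unc"
    df["p_fdr"] = np.nan
    df["significant"] = False
    if ok.any():
        rej, p_adj, _, _ = multipletests(df.loc[ok, pcol], alpha=q, method="fdr_bh")
        df.loc[ok, "p_fdr"] = p_adj
        df.loc[ok, "significant"] = rej
    return df
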