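"""PCA reduction feeding linear DFA: the identity/arousal classification engine.

The pipeline follows the classical two-stage recipe for multi-parametric
call data: (1) principal components of the correlation matrix of the 22
acoustic parameters, retaining components with eigenvalue > 1 (loadings
above 0.700 flagged as the parameters driving a component); (2) an
independent linear discriminant analysis on the retained PC scores, with
resubstitution and leave-one-out accuracies, per-class exact binomial
tests against chance (100/k %), and Pearson correlations between
discriminant functions and PCs to attribute the classification to
parameter sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._lda import LinearDiscriminant
from .stats import TestResult, anova_per_parameter, binomial_above_chance, paired_t
from .stats import fisher_omnibus
from .synth import PARAMETER_COLUMNS

log = logging.getLogger(__name__)


@dataclass
class PCAResult:
    """Correlation-matrix PCA with the eigenvalue-above-1 retention rule."""

    eigenvalues: np.ndarray  # all, non-increasing
    retained: int
    loadings: pd.DataFrame  # parameter x retained component correlations
    scores: np.ndarray  # rows x retained components
    variance_explained: float  # % of total variance by retained set
    flagged: pd.DataFrame  # bool mask |loading| > loading_flag
    row_index: pd.Index  # rows of the input actually used (listwise)


@dataclass
class DFAResult:
    """Linear DFA accuracies with chance-level bookkeeping."""

    original_accuracy: float  # resubstitution, %
    loo_accuracy: float  # leave-one-out, %
    chance: float  # 100 / n_classes, %
    per_class: pd.DataFrame  # class, n, n_correct(orig/loo), binomial p
    confusion: pd.DataFrame  # original-classification counts
    df_pc_correlations: pd.DataFrame  # DF x PC Pearson r
    classes: np.ndarray = field(default_factory=lambda: np.empty(0))


def chance_percent(n_classes: int) -> tuple[float, int]:
    """Chance accuracy for k equiprobable classes: exact % and the rounded
    integer rendering used in reports."""
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    exact = 100.0 / n_classes
    return exact, int(round(exact))


def pca_reduce(ft: pd.DataFrame, loading_flag: float = 0.700,
               parameters: list[str] | None = None) -> PCAResult:
    """Standardize parameters and take principal components of the
    correlation matrix; retain components with eigenvalue > 1.

    Rows with any missing parameter are excluded listwise (logged).
    Constant columns are an error naming the column, as they have no
    correlation structure to decompose.
    """
    parameters = parameters if parameters is not None else [
        c for c in PARAMETER_COLUMNS if c in ft.columns
    ]
    data = ft[parameters].astype(float)
    complete = data.dropna()
    dropped = len(data) - len(complete)
    if dropped:
        log.info("pca_reduce: %d rows with missing values excluded listwise",
                 dropped)
    if len(complete) <= len(parameters):
        raise ValueError(
            f"PCA needs more rows ({len(complete)}) than parameters "
            f"({len(parameters)})"
        )
    X = complete.to_numpy()
    sd = X.std(axis=0, ddof=1)
    constant = [p for p, s in zip(parameters, sd) if not np.isfinite(s) or s <= 0]
    if constant:
        raise ValueError(f"constant parameter column(s): {constant}")
    Z = (X - X.mean(axis=0)) / sd
    corr = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # deterministic sign: strongest loading of each component positive
    flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0),
                         np.arange(evecs.shape[1])])
    flip[flip == 0] = 1.0
    evecs = evecs * flip
    retained = max(int((evals > 1.0).sum()), 1)
    cols = [f"PC{i + 1}" for i in range(retained)]
    loadings = pd.DataFrame(
        evecs[:, :retained] * np.sqrt(np.maximum(evals[:retained], 0.0)),
        index=parameters, columns=cols,
    )
    scores = Z @ evecs[:, :retained]
    return PCAResult(
        eigenvalues=evals,
        retained=retained,
        loadings=loadings,
        scores=scores,
        variance_explained=100.0 * float(evals[:retained].sum()) / len(parameters),
        flagged=loadings.abs() > loading_flag,
        row_index=complete.index,
    )


def dfa_classify(scores: np.ndarray, labels, p_chance: float | None = None
                 ) -> DFAResult:
    """Linear DFA on (PC) scores: resubstitution + leave-one-out accuracy,
    per-class binomial tests vs chance, DF-PC correlations, confusion."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    lda = LinearDiscriminant().fit(scores, labels)
    classes = lda.classes_
    k = classes.size
    chance_exact, _ = chance_percent(k)
    p_chance = p_chance if p_chance is not None else 1.0 / k

    pred = lda.predict(scores)
    pred_loo = lda.loo_predict()
    orig_acc = 100.0 * float(np.mean(pred == labels))
    loo_acc = 100.0 * float(np.mean(pred_loo == labels))

    rows = []
    for c in classes:
        m = labels == c
        n = int(m.sum())
        k_orig = int((pred[m] == c).sum())
        k_loo = int((pred_loo[m] == c).sum())
        rows.append({
            "class": c, "n": n,
            "n_correct_original": k_orig,
            "p_binomial_original": binomial_above_chance(k_orig, n, p_chance).p,
            "n_correct_loo": k_loo,
            "p_binomial_loo": binomial_above_chance(k_loo, n, p_chance).p,
        })
    per_class = pd.DataFrame(rows)

    confusion = pd.crosstab(
        pd.Series(labels, name="true"), pd.Series(pred, name="predicted")
    ).reindex(index=classes, columns=classes, fill_value=0)

    df_scores = lda.discriminant_scores(scores)
    n_df = df_scores.shape[1]
    corr = np.zeros((n_df, scores.shape[1]))
    for i in range(n_df):
        for j in range(scores.shape[1]):
            sd = df_scores[:, i].std() * scores[:, j].std()
            if sd > 0:
                corr[i, j] = float(np.corrcoef(df_scores[:, i], scores[:, j])[0, 1])
    df_pc = pd.DataFrame(
        corr, index=[f"DF{i + 1}" for i in range(n_df)],
        columns=[f"PC{j + 1}" for j in range(scores.shape[1])],
    )
    return DFAResult(
        original_accuracy=orig_acc, loo_accuracy=loo_acc, chance=chance_exact,
        per_class=per_class, confusion=confusion, df_pc_correlations=df_pc,
        classes=classes,
    )


# ---------------------------------------------------------------------------
# the two study analyses
# ---------------------------------------------------------------------------


def identity_analysis(ft: pd.DataFrame, condition: str | None = None,
                      loading_flag: float = 0.700) -> dict:
    """Sender-identity battery for one arousal condition.

    Per-parameter one-way ANOVA across kittens with a Fisher-omnibus
    gatekeeper, PCA (eigenvalue > 1), DFA on the retained PC scores with
    leave-one-out cross-validation, per-kitten binomial tests against the
    1/k chance level, and the DF-PC correlation table.
    """
    sub = ft[ft["condition"] == condition] if condition is not None else ft
    if sub["kitten_id"].nunique() < 2:
        raise ValueError("identity analysis needs at least 2 kittens")
    anova, omnibus = anova_per_parameter(sub, group="kitten_id")
    pca = pca_reduce(sub, loading_flag=loading_flag)
    labels = sub.loc[pca.row_index, "kitten_id"].to_numpy()
    dfa = dfa_classify(pca.scores, labels)
    return {
        "condition": condition,
        "n_calls": int(len(pca.row_index)),
        "n_kittens": int(sub["kitten_id"].nunique()),
        "anova": anova,
        "fisher_omnibus": omnibus,
        "pca": pca,
        "dfa": dfa,
    }


ARROW_UP, ARROW_DOWN = "↑", "↓"


def arousal_analysis(ft: pd.DataFrame, loading_flag: float = 0.700,
                     alpha: float = 0.05) -> dict:
    """Arousal battery on per-kitten condition means.

    Each parameter is averaged per kitten and condition; conditions are
    compared with dependent t-tests (Fisher omnibus as gatekeeper) and a
    direction arrow is assigned to significant parameters. A PCA of the
    mean rows feeds a two-class DFA with leave-one-out cross-validation
    and per-condition binomial tests against the 50 % chance level.
    """
    params = [c for c in PARAMETER_COLUMNS if c in ft.columns]
    means = (ft.groupby(["kitten_id", "condition"], sort=True)[params]
             .mean().reset_index())
    wide_ok = means.pivot(index="kitten_id", columns="condition", values=params[0])
    complete_kittens = wide_ok.dropna().index
    excluded = sorted(set(means["kitten_id"]) - set(complete_kittens))
    if excluded:
        log.info("arousal_analysis: kittens lacking a condition dropped: %s",
                 excluded)
    means = means[means["kitten_id"].isin(complete_kittens)]
    n_kittens = len(complete_kittens)

    rows = []
    pvals = []
    for p in params:
        wide = means.pivot(index="kitten_id", columns="condition", values=p)
        if n_kittens < 2 or not {"Low", "High"} <= set(wide.columns):
            rows.append({"parameter": p, "t": np.nan, "p": np.nan,
                         "mean_low": np.nan, "mean_high": np.nan,
                         "sd_low": np.nan, "sd_high": np.nan, "direction": ""})
            continue
        low, high = wide["Low"].to_numpy(), wide["High"].to_numpy()
        keep = ~(np.isnan(low) | np.isnan(high))
        res = paired_t(low[keep], high[keep]) if keep.sum() >= 2 else TestResult(
            np.nan, np.nan, note="insufficient n")
        direction = ""
        if np.isfinite(res.p) and res.p <= alpha:
            direction = ARROW_UP if high[keep].mean() > low[keep].mean() else ARROW_DOWN
        rows.append({
            "parameter": p, "t": res.statistic, "p": res.p,
            "mean_low": float(np.nanmean(low)), "sd_low": float(np.nanstd(low, ddof=1)),
            "mean_high": float(np.nanmean(high)), "sd_high": float(np.nanstd(high, ddof=1)),
            "direction": direction,
        })
        if np.isfinite(res.p) and res.p > 0:
            pvals.append(res.p)
    ttests = pd.DataFrame(rows)
    omnibus = fisher_omnibus(pvals) if pvals else None

    report = {
        "n_kittens": n_kittens,
        "excluded_kittens": excluded,
        "t_tests": ttests,
        "fisher_omnibus": omnibus,
        "pca": None, "dfa": None, "scatter": None,
    }
    if n_kittens >= 2 and len(means) > len(params):
        pca = pca_reduce(means, loading_flag=loading_flag)
        labels = means.loc[pca.row_index, "condition"].to_numpy()
        dfa = dfa_classify(pca.scores, labels)
        scatter = pd.DataFrame({
            "kitten_id": means.loc[pca.row_index, "kitten_id"].to_numpy(),
            "condition": labels,
            "PC1": pca.scores[:, 0],
            "PC2": pca.scores[:, 1] if pca.scores.shape[1] > 1 else np.nan,
        })
        report.update({"pca": pca, "dfa": dfa, "scatter": scatter})
    else:
        log.info("arousal_analysis: insufficient rows for PCA+DFA "
                 "(%d kittens, %d mean rows)", n_kittens, len(means))
    return report
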