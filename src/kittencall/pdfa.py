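"""Permuted discriminant function analysis (pDFA) for non-independent data.

Calls from one individual are not independent samples, so a plain DFA
p-value overstates significance. The permuted DFA builds the null
distribution of the classification accuracy by re-running the identical
(balanced) DFA on datasets where the test-factor labels are permuted in
blocks that respect the data's dependence structure:

* crossed design (e.g. subject as test factor, arousal condition as
  control factor): the observed statistic uses data balanced across
  control levels; the null permutes subject labels across subject-by-
  condition blocks *within* each control level, so all calls of one
  subject in one condition move together.

* nested design (e.g. subject as test factor nested in litter as group
  factor): a balanced random selection of test-factor levels per group is
  drawn (averaged over selections); the null permutes subject labels
  across sub-blocks *within* each group, preserving the group structure
  so group-level differences cannot masquerade as individual signatures.

p-values include the observed arrangement (add-one rule), so the minimum
attainable p is 1/(1 + n_permutations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._lda import fast_lda_eval
from .synth import PARAMETER_COLUMNS

log = logging.getLogger(__name__)


@dataclass
class PDFAResult:
    design: str  # "crossed" | "nested"
    observed_original: float  # %
    observed_loo: float  # %
    null_original: np.ndarray  # per-permutation accuracies (%)
    null_loo: np.ndarray
    p_original: float
    p_loo: float
    n_permutations: int
    n_selections: int
    seed: int
    n_rows_used: int
    chance: float  # %

    def __post_init__(self) -> None:
        assert len(self.null_original) == self.n_permutations


def _perm_p(observed: float, null: np.ndarray) -> float:
    if null.size == 0:
        return float("nan")
    return (1.0 + float(np.sum(null >= observed - 1e-12))) / (1.0 + null.size)


def _pc_scores(X: np.ndarray) -> np.ndarray:
    """Correlation-matrix PC scores, components with eigenvalue > 1."""
    sd = X.std(axis=0, ddof=1)
    sd[sd <= 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    corr = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    retained = max(int((evals > 1.0).sum()), 1)
    return Z @ evecs[:, :retained]


def _run_design(
    ft: pd.DataFrame,
    test_factor: str,
    within_factor: str,
    design: str,
    n_perm: int,
    seed: int,
    n_selections: int,
    select_rows,
    parameters: list[str],
) -> PDFAResult:
    """Shared engine: balanced selections, observed + permuted accuracies."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xD0FA)))
    obs_o = np.zeros(n_selections)
    obs_l = np.zeros(n_selections)
    null_o = np.zeros((n_selections, n_perm))
    null_l = np.zeros((n_selections, n_perm))
    n_rows = 0
    n_classes_sel = 0
    for s in range(n_selections):
        sel = select_rows(rng)
        n_rows = len(sel)
        X = sel[parameters].to_numpy(dtype=float)
        scores = _pc_scores(X)
        sel_classes, codes = np.unique(sel[test_factor], return_inverse=True)
        n_classes_sel = sel_classes.size
        class_code = {c: i for i, c in enumerate(sel_classes)}
        obs_o[s], obs_l[s] = fast_lda_eval(scores, codes, n_classes_sel)
        # block structure: per control group, the block label arrays to
        # shuffle, and for each row which block it belongs to
        blocks = (sel[["block_id", within_factor, test_factor]]
                  .drop_duplicates("block_id").reset_index(drop=True))
        block_pos = {b: i for i, b in enumerate(blocks["block_id"])}
        row_block = np.array([block_pos[b] for b in sel["block_id"]])
        block_codes = np.array([class_code[c] for c in blocks[test_factor]])
        group_slices = [
            grp.index.to_numpy()
            for _, grp in blocks.groupby(within_factor, sort=True)
        ]
        for p in range(n_perm):
            perm_block_codes = block_codes.copy()
            for idx in group_slices:
                perm_block_codes[idx] = perm_block_codes[rng.permutation(idx)]
            perm_codes = perm_block_codes[row_block]
            try:
                null_o[s, p], null_l[s, p] = fast_lda_eval(
                    scores, perm_codes, n_classes_sel)
            except ValueError:  # a class lost all its blocks in this shuffle
                null_o[s, p], null_l[s, p] = np.nan, np.nan
    observed_original = float(obs_o.mean())
    observed_loo = float(obs_l.mean())
    null_original = np.nanmean(null_o, axis=0) if n_perm else np.empty(0)
    null_loo = np.nanmean(null_l, axis=0) if n_perm else np.empty(0)
    return PDFAResult(
        design=design,
        observed_original=observed_original,
        observed_loo=observed_loo,
        null_original=null_original,
        null_loo=null_loo,
        p_original=_perm_p(observed_original, null_original),
        p_loo=_perm_p(observed_loo, null_loo),
        n_permutations=n_perm,
        n_selections=n_selections,
        seed=seed,
        n_rows_used=n_rows,
        chance=100.0 / max(n_classes_sel, 1),
    )


def crossed_pdfa(
    ft: pd.DataFrame,
    test_factor: str = "kitten_id",
    control_factor: str = "condition",
    n_perm: int = 1000,
    seed: int = 0,
    n_selections: int = 10,
    parameters: list[str] | None = None,
) -> PDFAResult:
    """Crossed pDFA: classify ``test_factor`` controlling for a crossed
    ``control_factor``.

    Every test level must appear in every control level. Per selection, an
    equal number of calls (the smallest cell size) is drawn per test x
    control cell; the null permutes test labels across cells within each
    control level, cells moving as blocks.
    """
    if n_perm and n_perm < 100:
        log.warning("crossed_pdfa: %d permutations is low; p-values are "
                    "coarse (minimum 1/%d)", n_perm, n_perm + 1)
    parameters = parameters if parameters is not None else [
        c for c in PARAMETER_COLUMNS if c in ft.columns
    ]
    data = ft.dropna(subset=parameters).copy()
    cell = data.groupby([test_factor, control_factor], sort=True).size().unstack()
    if cell.isna().any().any() or (cell < 2).any().any():
        bad = cell[cell.isna().any(axis=1) | (cell < 2).any(axis=1)].index.tolist()
        raise ValueError(
            f"crossed design unbalanced beyond repair: test levels {bad} lack "
            f">=2 calls in every control level"
        )
    n_cell = int(cell.min().min())
    data["block_id"] = (data[test_factor].astype(str) + "|"
                        + data[control_factor].astype(str))

    def select_rows(rng: np.random.Generator) -> pd.DataFrame:
        parts = [
            grp.iloc[rng.choice(len(grp), n_cell, replace=False)]
            for _, grp in data.groupby("block_id", sort=True)
        ]
        return pd.concat(parts, ignore_index=True)

    return _run_design(data, test_factor, control_factor, "crossed",
                       n_perm, seed, n_selections, select_rows, parameters)


def nested_pdfa(
    ft: pd.DataFrame,
    test_factor: str = "kitten_id",
    group_factor: str = "litter_id",
    n_perm: int = 1000,
    seed: int = 0,
    n_selections: int = 100,
    sub_block_factor: str | None = "condition",
    parameters: list[str] | None = None,
) -> PDFAResult:
    """Nested pDFA: classify ``test_factor`` whose levels are nested in
    ``group_factor`` (e.g. kittens in litters).

    Per selection, an equal number of test levels is drawn per group (so no
    group dominates); the null permutes test labels across sub-blocks
    (test x ``sub_block_factor`` cells, or split halves when absent) within
    each group-by-sub-block stratum, so every permuted class keeps the same
    sub-block composition as an observed class (without the stratification
    a permuted class could combine e.g. two same-condition blocks and the
    null would be conservative). Groups contributing a single test level
    are excluded (logged).
    """
    parameters = parameters if parameters is not None else [
        c for c in PARAMETER_COLUMNS if c in ft.columns
    ]
    data = ft.dropna(subset=parameters).copy()
    level_group = data.groupby(test_factor, sort=True)[group_factor].nunique()
    if (level_group > 1).any():
        bad = level_group[level_group > 1].index.tolist()
        raise ValueError(f"test levels in multiple groups: {bad}")
    per_group = (data.drop_duplicates(test_factor)
                 .groupby(group_factor, sort=True)[test_factor].count())
    keep_groups = per_group[per_group >= 2].index
    excluded = sorted(set(per_group.index) - set(keep_groups))
    if excluded:
        log.info("nested_pdfa: groups with a single test level excluded: %s",
                 excluded)
    if len(keep_groups) < 2:
        raise ValueError("nested design needs >= 2 groups with >= 2 levels")
    data = data[data[group_factor].isin(keep_groups)].copy()
    n_levels = int(per_group[keep_groups].min())

    if sub_block_factor is not None and sub_block_factor in data.columns:
        sub = data[sub_block_factor].astype(str)
    else:  # split each test level's calls into two half blocks
        halves = []
        for _, grp in data.groupby(test_factor, sort=True):
            h = np.zeros(len(grp), dtype=int)
            h[len(grp) // 2:] = 1
            halves.append(pd.Series(h, index=grp.index))
        sub = pd.concat(halves).sort_index().astype(str)
    data["block_id"] = data[test_factor].astype(str) + "|" + sub
    data["perm_stratum"] = data[group_factor].astype(str) + "|" + sub
    n_call = int(data.groupby(test_factor, sort=True).size().min())

    def select_rows(rng: np.random.Generator) -> pd.DataFrame:
        chosen = []
        for _, grp in data.drop_duplicates(test_factor).groupby(
                group_factor, sort=True):
            levels = grp[test_factor].to_numpy()
            chosen.extend(rng.choice(levels, n_levels, replace=False))
        sub = data[data[test_factor].isin(chosen)]
        parts = [
            grp.iloc[rng.choice(len(grp), min(n_call, len(grp)), replace=False)]
            for _, grp in sub.groupby(test_factor, sort=True)
        ]
        return pd.concat(parts, ignore_index=True)

    return _run_design(data, test_factor, "perm_stratum", "nested",
                       n_perm, seed, n_selections, select_rows, parameters)
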