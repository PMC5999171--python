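"""Cohort-level scoring workflows shared by the CLI and analyses."""

from __future__ import annotations

from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from .bethesda import meets_revised_bethesda
from .cohort import GENES, Cohort
from .errors import NotApplicableError
from .scoring import CoefficientSet, score_mmrpredict, score_premm5
from .updating import UpdatedModel, build_update_dataset, predict_updated

__all__ = ["load_default_coeffs", "score_cohort", "score_cohort_updated"]

_DEFAULTS = {"premm5": "premm5_synthetic.yaml",
             "mmrpredict": "mmrpredict_synthetic.yaml"}


def load_default_coeffs(model: str) -> CoefficientSet:
    """Load one of the shipped (synthetic-valued) coefficient configs."""
    if model not in _DEFAULTS:
        raise KeyError(f"model must be one of {sorted(_DEFAULTS)}")
    ref = resources.files("lynchpred.configs") / _DEFAULTS[model]
    with resources.as_file(ref) as path:
        return CoefficientSet.from_yaml(path)


def score_cohort(cohort: Cohort,
                 premm5: Optional[CoefficientSet] = None,
                 mmrpredict: Optional[CoefficientSet] = None,
                 bethesda: bool = True) -> pd.DataFrame:
    """Score every proband; returns the cohort frame plus score columns.

    Columns appended (when the corresponding model is given): p_mlh1,
    p_msh2, p_msh6, p_pms2, p_overall; mmrpredict_p; bethesda_flag.
    Probands a model does not apply to get NaN in its columns.
    """
    df = cohort.to_frame()
    if premm5 is not None:
        probs = [score_premm5(p, premm5) for p in cohort]
        df["p_mlh1"] = [g.p_mlh1 for g in probs]
        df["p_msh2"] = [g.p_msh2 for g in probs]
        df["p_msh6"] = [g.p_msh6 for g in probs]
        df["p_pms2"] = [g.p_pms2 for g in probs]
        df["p_overall"] = [g.p_overall for g in probs]
    if mmrpredict is not None:
        vals = []
        for p in cohort:
            try:
                vals.append(score_mmrpredict(p, mmrpredict))
            except NotApplicableError:
                vals.append(np.nan)
        df["mmrpredict_p"] = vals
    if bethesda:
        flags = []
        for p in cohort:
            try:
                flags.append(meets_revised_bethesda(p).fulfilled)
            except NotApplicableError:
                flags.append(False)
        df["bethesda_flag"] = flags
    return df


def score_cohort_updated(cohort: Cohort, coeffs: CoefficientSet,
                         model: UpdatedModel) -> pd.DataFrame:
    """Score every proband under an updated four-gene model."""
    data = build_update_dataset(cohort, coeffs)
    df = cohort.to_frame()
    cols = {f"p_{g.lower()}": [] for g in GENES}
    overall = []
    for i in range(data.n):
        g = predict_updated(model, data.lp[i], data.proximal[i], data.two_plus[i])
        for gene, p in g.per_gene().items():
            cols[f"p_{gene.lower()}"].append(p)
        overall.append(g.p_overall)
    for c, v in cols.items():
        df[c] = v
    df["p_overall"] = overall
    return df
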