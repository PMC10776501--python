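"""Sample metadata, stratified train/test split, baseline comparisons.

The study design splits a cancer/healthy cohort 7:3 into training and
testing sets, stratified by class so both arms keep the case:control
balance, and compares baseline covariates (sex, BMI class by Fisher's
exact test; age by Mann-Whitney) between cases and controls within each
arm.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError

LABELS = ("cancer", "healthy")
CANCER_TYPES = ("lung", "gastrointestinal", "other")
STAGES = ("II", "III", "IV")
SEXES = ("M", "F")
BMI_CLASSES = ("<=24", ">24")
RESPONSES = ("response", "non_response")


@dataclass(frozen=True)
class SampleMeta:
    """Clinical labels for one participant.

    Healthy samples carry no stage/cancer type/response; a response
    label is only defined for samples that received immunotherapy.
    """

    sample_id: str
    label: str
    cancer_type: str | None = None
    stage: str | None = None
    age: float | None = None
    sex: str | None = None
    bmi_class: str | None = None
    immunotherapy: bool = False
    response: str | None = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"{self.sample_id}: label must be one of {LABELS}")
        if self.label == "healthy":
            if self.cancer_type or self.stage or self.response or self.immunotherapy:
                raise ValueError(
                    f"{self.sample_id}: healthy samples cannot carry cancer_type/stage/"
                    "immunotherapy/response"
                )
        else:
            if self.cancer_type is not None and self.cancer_type not in CANCER_TYPES:
                raise ValueError(f"{self.sample_id}: unknown cancer_type {self.cancer_type!r}")
            if self.stage is not None and self.stage not in STAGES:
                raise ValueError(f"{self.sample_id}: unknown stage {self.stage!r}")
        if self.response is not None:
            if not self.immunotherapy:
                raise ValueError(
                    f"{self.sample_id}: response label without immunotherapy"
                )
            if self.response not in RESPONSES:
                raise ValueError(f"{self.sample_id}: unknown response {self.response!r}")
        if self.sex is not None and self.sex not in SEXES:
            raise ValueError(f"{self.sample_id}: unknown sex {self.sex!r}")
        if self.bmi_class is not None and self.bmi_class not in BMI_CLASSES:
            raise ValueError(f"{self.sample_id}: unknown bmi_class {self.bmi_class!r}")


@dataclass(frozen=True)
class CohortSplit:
    """Stratified train/test partition of sample ids."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    ratio: float
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")


_SHEET_COLUMNS = [
    "sample_id",
    "label",
    "cancer_type",
    "stage",
    "age",
    "sex",
    "bmi_class",
    "immunotherapy",
    "response",
]
_REQUIRED = {"sample_id", "label"}


def _cell(value):
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    s = str(value).strip()
    return s if s not in ("", "NA", "nan", "None") else None


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Parse and validate a TSV sample sheet into :class:`SampleMeta` records."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = _REQUIRED - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing required columns {sorted(missing)}")
    metas: list[SampleMeta] = []
    seen: set[str] = set()
    for row_no, row in enumerate(df.to_dict("records"), start=2):
        sid = _cell(row.get("sample_id"))
        if sid is None:
            raise InputError(f"{path}:{row_no}: empty sample_id")
        if sid in seen:
            raise InputError(f"{path}:{row_no}: duplicate sample_id {sid!r}")
        seen.add(sid)
        age = _cell(row.get("age"))
        immuno = _cell(row.get("immunotherapy"))
        try:
            metas.append(
                SampleMeta(
                    sample_id=sid,
                    label=_cell(row.get("label")) or "",
                    cancer_type=_cell(row.get("cancer_type")),
                    stage=_cell(row.get("stage")),
                    age=float(age) if age is not None else None,
                    sex=_cell(row.get("sex")),
                    bmi_class=_cell(row.get("bmi_class")),
                    immunotherapy=str(immuno).lower() in ("true", "1", "yes"),
                    response=_cell(row.get("response")),
                )
            )
        except ValueError as exc:
            raise InputError(f"{path}:{row_no}: {exc}") from exc
    return metas


def write_sample_sheet(metas: Sequence[SampleMeta], path: str | Path) -> None:
    rows = []
    for m in metas:
        rows.append(
            {
                "sample_id": m.sample_id,
                "label": m.label,
                "cancer_type": m.cancer_type or "",
                "stage": m.stage or "",
                "age": "" if m.age is None else f"{m.age:g}",
                "sex": m.sex or "",
                "bmi_class": m.bmi_class or "",
                "immunotherapy": str(m.immunotherapy),
                "response": m.response or "",
            }
        )
    pd.DataFrame(rows, columns=_SHEET_COLUMNS).to_csv(path, sep="\t", index=False)


def stratified_split(
    metas: Sequence[SampleMeta], ratio: float = 0.7, seed: int = 0
) -> CohortSplit:
    """Class-stratified random split.

    Within each label class, samples are shuffled by ``seed`` and the
    first ``ceil(ratio * n_class)`` go to training. With 106 cancer and
    100 healthy at ratio 0.7 this yields the 75+70=145 / 31+30=61 design.
    """
    if not 0 < ratio < 1:
        raise ConfigurationError(f"ratio must be in (0, 1), got {ratio}")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for label in LABELS:
        ids = [m.sample_id for m in metas if m.label == label]
        if not ids:
            raise ConfigurationError(f"class {label!r} has no samples; cannot stratify")
        order = rng.permutation(len(ids))
        n_train = math.ceil(ratio * len(ids))
        shuffled = [ids[i] for i in order]
        train.extend(shuffled[:n_train])
        test.extend(shuffled[n_train:])
    return CohortSplit(train_ids=tuple(train), test_ids=tuple(test), ratio=ratio, seed=seed)


def write_split(split: CohortSplit, path: str | Path) -> None:
    rows = [{"sample_id": s, "cohort": "train"} for s in split.train_ids]
    rows += [{"sample_id": s, "cohort": "test"} for s in split.test_ids]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_split(path: str | Path, ratio: float = 0.7, seed: int = -1) -> CohortSplit:
    df = pd.read_csv(path, sep="\t", dtype=str)
    train = tuple(df.loc[df["cohort"] == "train", "sample_id"])
    test = tuple(df.loc[df["cohort"] == "test", "sample_id"])
    return CohortSplit(train_ids=train, test_ids=test, ratio=ratio, seed=seed)


def _fisher_2x2(table: np.ndarray) -> tuple[float, float]:
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for small tie-free samples, else
    normal approximation with tie and continuity corrections."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    no_ties = np.unique(np.concatenate([x, y])).size == x.size + y.size
    method = "exact" if (x.size <= 12 and y.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def baseline_table(metas: Sequence[SampleMeta], split: CohortSplit) -> pd.DataFrame:
    """Cancer-vs-healthy baseline comparisons within each split arm.

    Sex and BMI class are compared by Fisher's exact test on the 2x2
    contingency table; age by the Mann-Whitney test. Covariates missing
    for every compared sample are omitted with a warning.
    """
    by_id = {m.sample_id: m for m in metas}
    rows = []
    for cohort, ids in (("train", split.train_ids), ("test", split.test_ids)):
        group = [by_id[s] for s in ids]
        cancer = [m for m in group if m.label == "cancer"]
        healthy = [m for m in group if m.label == "healthy"]
        for covariate, levels in (("sex", SEXES), ("bmi_class", BMI_CLASSES)):
            vals_c = [getattr(m, covariate) for m in cancer if getattr(m, covariate)]
            vals_h = [getattr(m, covariate) for m in healthy if getattr(m, covariate)]
            if not vals_c and not vals_h:
                warnings.warn(f"{cohort}: covariate {covariate!r} all missing; omitted")
                continue
            table = np.array(
                [
                    [vals_c.count(levels[0]), vals_c.count(levels[1])],
                    [vals_h.count(levels[0]), vals_h.count(levels[1])],
                ]
            )
            odds, p = _fisher_2x2(table)
            rows.append(
                {
                    "cohort": cohort,
                    "covariate": covariate,
                    "test": "fisher_exact",
                    "statistic": odds,
                    "p_value": p,
                }
            )
        ages_c = [m.age for m in cancer if m.age is not None]
        ages_h = [m.age for m in healthy if m.age is not None]
        if ages_c and ages_h:
            u, p = mann_whitney(ages_c, ages_h)
            rows.append(
                {
                    "cohort": cohort,
                    "covariate": "age",
                    "test": "mann_whitney",
                    "statistic": u,
                    "p_value": p,
                }
            )
        else:
            warnings.warn(f"{cohort}: covariate 'age' all missing; omitted")
    return pd.DataFrame(rows, columns=["cohort", "covariate", "test", "statistic", "p_value"])
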