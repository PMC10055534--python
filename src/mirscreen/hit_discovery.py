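"""Hit ranking, compound-class profiling and miRNA co-regulation analysis.

The primary readout of the screen is a *waterfall*: compounds on one plate
ordered by descending log2 fold change of a chosen miRNA, a compound's
position in that ordering being its *plate rank*.  Hit selection uses the
plate rank as the primary criterion and adjusts it with annotation-based
secondary criteria (clinical use, blood-brain-barrier permeability, prior
evidence) and a specificity score counting how many other miRNAs a compound
perturbs.

Class profiles ask whether a pharmacological class (e.g. Na+/K+-ATPase
inhibitors) shifts a miRNA coherently: the statistic is the median log2
fold change across class members, and significance comes from a
permutation null that resamples size-matched compound sets from the whole
library (two-sided, +1/(B+1)-corrected, Benjamini-Hochberg across miRNAs
within each class).  The permutation null is an extension beyond simple
per-class summaries: it turns the class heatmap into a testable claim.

Correlation maps over compound wells reveal co-regulated miRNAs — the
signature of a shared transcriptional unit such as the miR-132/212 locus —
as strongly positively correlated responses across the compound library.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from mirscreen.plate_io import CompoundAnnotation, ValidationError
from mirscreen.normalize import NormalizedScreen

__all__ = [
    "WaterfallResult",
    "ClassProfile",
    "CorrelationMap",
    "waterfall_rank",
    "select_hits",
    "class_profile",
    "mirna_correlation_map",
    "top_correlates",
]


@dataclass
class WaterfallResult:
    """Per-plate compound ordering for one miRNA.

    ``plates`` maps plate/group id to a DataFrame with columns
    ``compound_id, log2fc, rank`` sorted by rank (1 = strongest inducer);
    ranks form a permutation of 1..n within each plate.  ``controls`` holds
    vehicle and positive-control well values for display alongside — they
    never enter the compound ranking.
    """

    mirna_id: str
    grouping: str
    plates: dict[str, pd.DataFrame]
    controls: pd.DataFrame

    def best_rank(self) -> pd.Series:
        """Minimum (best) plate rank per compound across all plates."""
        frames = [df[["compound_id", "rank"]] for df in self.plates.values()]
        allr = pd.concat(frames, ignore_index=True)
        return allr.groupby("compound_id")["rank"].min()


def _compound_log2fc(normalized: NormalizedScreen) -> pd.DataFrame:
    """miRNA x compound log2fc matrix (wells of one compound averaged)."""
    comp_wells = normalized.compound_wells()
    if not comp_wells:
        raise ValidationError("no compound wells in normalized screen")
    cols = normalized.log2fc[[w.well_id for w in comp_wells]]
    mapping = {w.well_id: w.compound_id for w in comp_wells}
    return cols.T.groupby(cols.columns.map(mapping)).mean().T


def waterfall_rank(
    normalized: NormalizedScreen,
    mirna_id: str,
    grouping: str = "sequencing_plate",
) -> WaterfallResult:
    """Rank compounds by descending log2fc of one miRNA within each plate.

    ``grouping='sequencing_plate'`` groups by sequencing batch (the pooled
    384-barcode unit); ``'culture_plate'`` groups by the physical 96-well
    plate.  Ties break lexicographically by compound id, so ranks are a
    deterministic permutation of 1..n.  Compounds with several wells in a
    group are ranked on their mean log2fc.
    """
    if mirna_id not in normalized.log2fc.index:
        raise ValidationError(f"miRNA {mirna_id!r} not in normalized layer")
    if grouping not in ("sequencing_plate", "culture_plate"):
        raise ValueError(f"unknown grouping {grouping!r}")
    attr = "batch_id" if grouping == "sequencing_plate" else "plate_id"
    values = normalized.log2fc.loc[mirna_id]
    plates: dict[str, pd.DataFrame] = {}
    control_rows = []
    groups: dict[str, list] = {}
    for well in normalized.wells:
        if well.treatment_role == "compound":
            groups.setdefault(getattr(well, attr), []).append(well)
        else:
            control_rows.append(
                {
                    "plate": getattr(well, attr),
                    "well_id": well.well_id,
                    "treatment_role": well.treatment_role,
                    "log2fc": values[well.well_id],
                }
            )
    for plate, wells in sorted(groups.items()):
        per_compound: dict[str, list[float]] = {}
        for w in wells:
            per_compound.setdefault(w.compound_id, []).append(values[w.well_id])
        rows = [
            {"compound_id": cid, "log2fc": float(np.mean(v))}
            for cid, v in per_compound.items()
        ]
        df = pd.DataFrame(rows).sort_values(
            by=["log2fc", "compound_id"], ascending=[False, True]
        )
        df["rank"] = np.arange(1, len(df) + 1)
        plates[plate] = df.reset_index(drop=True)
    controls = pd.DataFrame(
        control_rows, columns=["plate", "well_id", "treatment_role", "log2fc"]
    )
    return WaterfallResult(mirna_id, grouping, plates, controls)


def select_hits(
    waterfall: WaterfallResult,
    annotations: Mapping[str, CompoundAnnotation],
    normalized: NormalizedScreen,
    top_n: int = 44,
    rank_cut: int | None = None,
    specificity_threshold: float = 1.0,
) -> pd.DataFrame:
    """Order candidate hits by plate rank, then secondary criteria.

    Primary score: best plate rank of the compound for the waterfall's
    miRNA.  Secondary flags (all from annotations): in clinical use,
    BBB-permeable, prior evidence of the sought activity.  Specificity is
    the number of *other* miRNAs the compound moves beyond
    ``|log2fc| > specificity_threshold`` — lower means more specific.
    Unannotated compounds are retained but satisfy no secondary flag.
    Final order: (rank, more flags first, more specific first, id).
    """
    best = waterfall.best_rank()
    if rank_cut is not None:
        best = best[best <= rank_cut]
    comp_fc = _compound_log2fc(normalized)
    others = comp_fc.drop(index=waterfall.mirna_id, errors="ignore")
    off_target = (others.abs() > specificity_threshold).sum(axis=0)
    rows = []
    for cid, rank in best.items():
        ann = annotations.get(cid)
        flags = {
            "in_clinical_use": bool(ann.in_clinical_use) if ann else False,
            "bbb_permeable": (ann.bbb_permeable == "yes") if ann else False,
            "prior_evidence": bool(ann.prior_evidence) if ann else False,
        }
        rows.append(
            {
                "compound_id": cid,
                "name": ann.name if ann else "",
                "target_class": ann.target_class if ann else "",
                "plate_rank": int(rank),
                **flags,
                "n_secondary": sum(flags.values()),
                "specificity": int(off_target.get(cid, 0)),
                "log2fc": float(
                    comp_fc.loc[waterfall.mirna_id, cid]
                    if cid in comp_fc.columns
                    else np.nan
                ),
                "annotated": ann is not None,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table = table.sort_values(
        by=["plate_rank", "n_secondary", "specificity", "compound_id"],
        ascending=[True, False, True, True],
    ).reset_index(drop=True)
    return table.head(top_n)


@dataclass
class ClassProfile:
    """Median log2fc profile of one compound class with its permutation null."""

    label: str
    members: list[str]
    table: pd.DataFrame  # index miRNA; columns median_log2fc, p_value, q_value
    n_permutations: int
    seed: int

    @property
    def n_members(self) -> int:
        return len(self.members)


def _class_labels(
    annotations: Mapping[str, CompoundAnnotation],
    compound_ids: Sequence[str],
    class_field: str,
) -> dict[str, list[str]]:
    """Map class label -> member compound ids; multi-label via ';'."""
    classes: dict[str, list[str]] = {}
    for cid in compound_ids:
        ann = annotations.get(cid)
        if ann is None:
            continue
        raw = getattr(ann, class_field, "")
        for label in (part.strip() for part in str(raw).split(";")):
            if label:
                classes.setdefault(label, []).append(cid)
    return classes


def class_profile(
    normalized: NormalizedScreen,
    annotations: Mapping[str, CompoundAnnotation],
    class_field: str = "target_class",
    min_class_size: int = 5,
    B: int = 10000,
    seed: int = 0,
    classes: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, ClassProfile]:
    """Per-class median log2fc with size-matched permutation p-values.

    For each class with at least ``min_class_size`` members on the screen,
    the observed statistic is the median log2fc of member compounds per
    miRNA.  The null resamples ``B`` random compound sets of the same size
    from the whole library (positive-control and vehicle wells excluded);
    p = (#{|perm| >= |obs|} + 1) / (B + 1), two-sided, so p is never zero.
    Benjamini-Hochberg q-values are computed across miRNAs within each
    class.  ``classes`` overrides the annotation-derived label map (used
    for calibration studies with arbitrary labelings).
    """
    if B < 100:
        raise ValueError("B < 100 gives an unstable permutation null")
    comp_fc = _compound_log2fc(normalized)
    compound_ids = list(comp_fc.columns)
    if classes is None:
        classes = _class_labels(annotations, compound_ids, class_field)
    X = comp_fc.to_numpy()
    n_compounds = X.shape[1]
    col_index = {cid: j for j, cid in enumerate(compound_ids)}
    rng = np.random.default_rng(seed)
    profiles: dict[str, ClassProfile] = {}
    for label in sorted(classes):
        members = [c for c in classes[label] if c in col_index]
        m = len(members)
        if m < min_class_size:
            warnings.warn(
                f"class {label!r} has {m} < {min_class_size} members on the "
                "screen; skipped",
                stacklevel=2,
            )
            continue
        obs = np.median(X[:, [col_index[c] for c in members]], axis=1)
        exceed = np.zeros(X.shape[0], dtype=np.int64)
        chunk = max(1, min(B, int(2e7 // (X.shape[0] * m) + 1)))
        done = 0
        while done < B:
            b = min(chunk, B - done)
            idx = np.argsort(rng.random((b, n_compounds)), axis=1)[:, :m]
            perm = np.median(X[:, idx], axis=2)  # (n_mirna, b)
            exceed += (np.abs(perm) >= np.abs(obs)[:, None]).sum(axis=1)
            done += b
        p = (exceed + 1) / (B + 1)
        q = multipletests(p, method="fdr_bh")[1]
        table = pd.DataFrame(
            {"median_log2fc": obs, "p_value": p, "q_value": q},
            index=comp_fc.index,
        )
        table.index.name = "mirna_id"
        profiles[label] = ClassProfile(label, members, table, B, seed)
    return profiles


@dataclass
class CorrelationMap:
    """Symmetric miRNA x miRNA correlation matrix over compound wells."""

    matrix: pd.DataFrame
    method: str
    subset: list[str] = field(default_factory=list)


def mirna_correlation_map(
    normalized: NormalizedScreen,
    subset: Sequence[str] | int | None = 20,
    method: str = "pearson",
) -> CorrelationMap:
    """Pairwise correlation of log2fc vectors across compound wells.

    ``subset`` is either an explicit miRNA list or an integer n selecting
    the n most abundant miRNAs by mean CPM (default 20, the unit shown in
    screen-level correlation maps); ``None`` uses all miRNAs.  Vehicle and
    positive-control wells are excluded.  A zero-variance miRNA gets
    missing (NaN) off-diagonal correlations, never 0; the diagonal is
    exactly 1.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    comp_wells = [w.well_id for w in normalized.compound_wells()]
    if len(comp_wells) < 3:
        raise ValidationError("need at least 3 compound wells for correlations")
    if subset is None:
        mirnas = list(normalized.log2fc.index)
    elif isinstance(subset, int):
        mean_cpm = normalized.cpm.mean(axis=1)
        mirnas = list(mean_cpm.sort_values(ascending=False).index[:subset])
    else:
        missing = [m for m in subset if m not in normalized.log2fc.index]
        if missing:
            raise ValidationError(f"miRNAs not in normalized layer: {missing}")
        mirnas = list(subset)
    data = normalized.log2fc.loc[mirnas, comp_wells].T
    matrix = data.corr(method=method)  # constant columns -> NaN
    np.fill_diagonal(matrix.values, 1.0)
    return CorrelationMap(matrix, method, mirnas)


def top_correlates(
    corr: CorrelationMap | pd.DataFrame, mirna_id: str, k: int = 10
) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    """The k most positively and k most negatively correlated miRNAs.

    Excludes the miRNA itself and missing correlations; lists are ordered
    by signed r (strongest first) and truncated when fewer than k partners
    exist.
    """
    matrix = corr.matrix if isinstance(corr, CorrelationMap) else corr
    if mirna_id not in matrix.index:
        raise ValidationError(f"miRNA {mirna_id!r} not in correlation map")
    row = matrix.loc[mirna_id].drop(labels=[mirna_id]).dropna()
    ordered = row.sort_values(ascending=False)
    positive = [(m, float(r)) for m, r in ordered.head(k).items() if r > 0]
    negative = [
        (m, float(r))
        for m, r in ordered.tail(k)[::-1].items()
        if r < 0
    ]
    return positive, negative
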