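"""Synthetic inputs with ground-truth bookkeeping for every pipeline stage.

The screen generator emulates a plate-based compound screen read out by
small-RNA sequencing of neurons: ~340 quantifiable miRNAs over 6 pooled
sequencing batches (4 x 96-well culture plates each), a mean library size
of 55,529 miRNA reads per well with log-normal spread, negative-binomial
count noise, multiplicative per-(batch, miRNA) batch effects, DMSO vehicle
and forskolin-style positive-control wells on every plate, a small
fraction of failed wells with near-zero library size, planted compound
effects, and a co-regulated miRNA pair modelling a shared transcriptional
unit (the miR-132/212 locus): the two members share every planted effect.

Everything is seeded: identical config + seed give byte-identical outputs.
The generator also emits FASTQ reads (to exercise trimming and
quantification end to end), 4PL dose-response tables and qPCR Ct tables,
each with the exact ground truth recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mirscreen.plate_io import (
    CompoundAnnotation,
    CountMatrix,
    ScreenDataset,
    ValidationError,
    WellRecord,
    assemble_screen,
)
from mirscreen.small_rna_quant import DEFAULT_ADAPTER, MiRNAReference
from mirscreen.validation_stats import four_pl

__all__ = [
    "ScreenSimConfig",
    "GroundTruth",
    "simulate_screen",
    "simulate_reference",
    "simulate_fastq",
    "simulate_dose_response",
    "simulate_qpcr",
]

#: Target/compound classes sampled for synthetic annotations.
CLASS_POOL = (
    "Na, K-ATPase inhibitor",
    "COX inhibitor",
    "VEGFR inhibitor",
    "EGFR inhibitor",
    "HDAC inhibitor",
    "adenylyl cyclase activator",
    "antiviral",
    "beta blocker",
    "calcium channel blocker",
    "SSRI",
)

INDICATION_POOL = (
    "heart failure",
    "hypertension",
    "infection",
    "oncology",
    "depression",
    "inflammation",
)


@dataclass(frozen=True)
class ScreenSimConfig:
    """Study conditions of the simulated screen.

    Defaults reproduce the structure of the real screen: 6 batches of four
    96-well culture plates pooled per sequencing run, 8 vehicle and 4
    positive-control wells per batch, mean library size 55,529, ~5% failed
    wells.  Compound ids are assigned deterministically in well order
    ("C0001", "C0002", ...) so planted effects can reference them.
    """

    seed: int
    n_mirnas: int = 340
    n_batches: int = 6
    plates_per_batch: int = 4
    wells_per_plate: int = 96
    vehicle_per_plate: int = 2
    positive_per_plate: int = 1
    mean_library_size: float = 55529.0
    library_sigma: float = 0.3
    nb_size: float = 20.0
    baseline_sigma: float = 2.0
    batch_sigma: float = 0.2
    failed_fraction: float = 0.05
    effects: tuple[tuple[str, tuple[str, ...], float], ...] = ()
    coreg_pair: tuple[str, str] | None = ("miR-132", "miR-212")
    #: baseline-abundance quantile at which the co-regulated pair is planted;
    #: the real locus sits in the top decile of detected species (rank ~26),
    #: which keeps its counting noise well below the planted effects
    coreg_abundance_quantile: float = 0.92
    positive_control_effect: float = 2.5
    dose: float = 10.0

    def __post_init__(self) -> None:
        positive = {
            "n_mirnas": self.n_mirnas,
            "n_batches": self.n_batches,
            "plates_per_batch": self.plates_per_batch,
            "wells_per_plate": self.wells_per_plate,
            "mean_library_size": self.mean_library_size,
            "nb_size": self.nb_size,
            "positive_control_effect": self.positive_control_effect,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if not 0.0 <= self.failed_fraction < 1.0:
            raise ValueError("failed_fraction must be in [0, 1)")
        for cid, mirnas, fold in self.effects:
            if fold <= 0:
                raise ValueError(f"effect fold for {cid} must be > 0, got {fold}")

    def mirna_ids(self) -> list[str]:
        width = max(3, len(str(self.n_mirnas)))
        return [f"miR-{i:0{width}d}" for i in range(1, self.n_mirnas + 1)]


@dataclass
class GroundTruth:
    """Exactly what the generator planted, for oracle-style tests."""

    proportions: pd.DataFrame  # expected miRNA proportions per well (sum to 1)
    batch_factors: pd.DataFrame  # miRNA x batch multiplicative factors
    effects: list[tuple[str, tuple[str, ...], float]]
    failed_wells: list[str]
    library_means: pd.Series
    compound_of_well: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "effects": [
                {"compound_id": c, "mirnas": list(m), "fold": f}
                for c, m, f in self.effects
            ],
            "failed_wells": self.failed_wells,
            "n_wells": self.proportions.shape[1],
        }


def _positions_96() -> list[str]:
    return [f"{r}{c:02d}" for r in "ABCDEFGH" for c in range(1, 13)]


def coregulation_effects(
    n_compounds: int,
    target: str = "miR-132",
    frequency: float = 0.25,
    fold_range: tuple[float, float] = (2.0, 6.0),
    seed: int = 0,
) -> tuple[tuple[str, tuple[str, ...], float], ...]:
    """Default planted-effect table for co-regulation studies.

    A bioactive library at screening concentration perturbs an
    activity-dependent miRNA locus broadly: a quarter of compounds move the
    target, with fold effects log-uniform between 2 and 6.  Compound ids
    follow the generator's deterministic "C0001..." assignment.  Because
    the generator shares every effect with the declared co-regulated
    partner, these effects drive both members of the pair.
    """
    rng = np.random.default_rng(seed)
    lo, hi = fold_range
    effects = []
    for i in range(1, n_compounds + 1):
        if rng.random() < frequency:
            fold = lo * (hi / lo) ** rng.random()
            effects.append((f"C{i:04d}", (target,), float(fold)))
    return tuple(effects)


def simulate_screen(config: ScreenSimConfig) -> tuple[ScreenDataset, GroundTruth]:
    """Draw one synthetic screen with full ground-truth bookkeeping.

    Per-well expected proportions are baseline x batch factor x planted
    compound effects, renormalized; counts are negative-binomial around
    library size x proportion.  Failed wells get a realized total drawn
    uniformly below 1,000 reads (multinomially distributed over miRNAs) so
    the low-count QC oracle is exact.  Vehicle wells carry no compound
    effect; positive-control wells induce the co-regulated pair by
    ``positive_control_effect``.  Failed wells are drawn among compound
    wells so every batch keeps its vehicle baseline.
    """
    rng = np.random.default_rng(config.seed)
    mirna_ids = config.mirna_ids()
    id_index = {m: i for i, m in enumerate(mirna_ids)}

    def expand_coreg(targets: Sequence[str]) -> tuple[str, ...]:
        # the co-regulated pair shares every effect touching either member
        out = set(targets)
        if config.coreg_pair and out & set(config.coreg_pair):
            out |= set(config.coreg_pair)
        return tuple(sorted(out))

    for cid, targets, fold in config.effects:
        for m in targets:
            if m not in id_index:
                raise ValidationError(f"effect for {cid} references unknown miRNA {m!r}")
    if config.coreg_pair:
        for m in config.coreg_pair:
            if m not in id_index:
                raise ValidationError(f"co-regulated pair references unknown miRNA {m!r}")

    baseline = rng.lognormal(0.0, config.baseline_sigma, config.n_mirnas)
    if config.coreg_pair:
        level = np.quantile(baseline, config.coreg_abundance_quantile)
        for m in config.coreg_pair:
            if m in id_index:
                baseline[id_index[m]] = level
    baseline /= baseline.sum()
    batch_ids = [f"B{b}" for b in range(1, config.n_batches + 1)]
    batch_factors = rng.lognormal(
        0.0, config.batch_sigma, (config.n_mirnas, config.n_batches)
    )

    if config.wells_per_plate != 96:
        raise ValueError("only the 96-well culture-plate geometry is generated")
    positions = _positions_96()
    n_controls = config.vehicle_per_plate + config.positive_per_plate
    if n_controls >= config.wells_per_plate:
        raise ValueError("more control wells than wells per plate")
    # fixed control layout: vehicles at the plate corners, positive mid-plate
    vehicle_pos = (
        [positions[0], positions[-1]]
        if config.vehicle_per_plate == 2
        else positions[: config.vehicle_per_plate]
    )
    positive_pos = positions[47 : 47 + config.positive_per_plate]

    wells: list[WellRecord] = []
    compound_counter = 0
    plate_counter = 0
    for batch_id in batch_ids:
        for _ in range(config.plates_per_batch):
            plate_counter += 1
            plate_id = f"P{plate_counter:02d}"
            for pos in positions:
                well_id = f"{plate_id}:{pos}"
                if pos in vehicle_pos:
                    role, cid = "vehicle", ""
                elif pos in positive_pos:
                    role, cid = "positive_control", "forskolin"
                else:
                    compound_counter += 1
                    role, cid = "compound", f"C{compound_counter:04d}"
                wells.append(
                    WellRecord(
                        well_id=well_id,
                        plate_id=plate_id,
                        position=pos,
                        batch_id=batch_id,
                        treatment_role=role,
                        compound_id=cid,
                        dose=config.dose if role != "vehicle" else 0.0,
                    )
                )

    effect_by_compound: dict[str, list[tuple[tuple[str, ...], float]]] = {}
    realized_effects: list[tuple[str, tuple[str, ...], float]] = []
    for cid, targets, fold in config.effects:
        expanded = expand_coreg(targets)
        effect_by_compound.setdefault(cid, []).append((expanded, fold))
        realized_effects.append((cid, expanded, fold))
    if config.coreg_pair:
        pc_targets = tuple(sorted(config.coreg_pair))
        effect_by_compound.setdefault("forskolin", []).append(
            (pc_targets, config.positive_control_effect)
        )
        realized_effects.append(
            ("forskolin", pc_targets, config.positive_control_effect)
        )

    # expected proportions per well
    n_wells = len(wells)
    props = np.empty((config.n_mirnas, n_wells))
    for j, well in enumerate(wells):
        b = batch_ids.index(well.batch_id)
        p = baseline * batch_factors[:, b]
        for targets, fold in effect_by_compound.get(well.compound_id, []):
            for m in targets:
                p[id_index[m]] *= fold
        props[:, j] = p / p.sum()

    compound_well_idx = [
        j for j, w in enumerate(wells) if w.treatment_role == "compound"
    ]
    n_failed = int(round(config.failed_fraction * n_wells))
    n_failed = min(n_failed, len(compound_well_idx))
    failed_idx = sorted(
        rng.choice(compound_well_idx, size=n_failed, replace=False).tolist()
    )
    failed_set = set(failed_idx)

    mu = np.log(config.mean_library_size) - config.library_sigma**2 / 2.0
    lib_means = np.exp(rng.normal(mu, config.library_sigma, n_wells))
    counts = np.empty((config.n_mirnas, n_wells), dtype=np.int64)
    for j in range(n_wells):
        if j in failed_set:
            total = int(rng.integers(0, 1000))
            counts[:, j] = rng.multinomial(total, props[:, j])
            lib_means[j] = total
        else:
            mean = lib_means[j] * props[:, j]
            p_nb = config.nb_size / (config.nb_size + mean)
            counts[:, j] = rng.negative_binomial(config.nb_size, p_nb)

    well_ids = [w.well_id for w in wells]
    matrix = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(mirna_ids, name="mirna_id"), columns=well_ids)
    )

    annotations = _simulate_annotations(
        [w.compound_id for w in wells if w.treatment_role == "compound"],
        rng,
    )
    annotations["forskolin"] = CompoundAnnotation(
        compound_id="forskolin",
        name="forskolin",
        pathway="cAMP",
        bbb_permeable="yes",
        target_class="adenylyl cyclase activator",
    )

    dataset = assemble_screen(matrix, wells, annotations)
    truth = GroundTruth(
        proportions=pd.DataFrame(props, index=mirna_ids, columns=well_ids),
        batch_factors=pd.DataFrame(
            batch_factors, index=mirna_ids, columns=batch_ids
        ),
        effects=realized_effects,
        failed_wells=[well_ids[j] for j in failed_idx],
        library_means=pd.Series(lib_means, index=well_ids, name="library_mean"),
        compound_of_well={w.well_id: w.compound_id for w in wells if w.compound_id},
    )
    return dataset, truth


def _simulate_annotations(
    compound_ids: Sequence[str], rng: np.random.Generator
) -> dict[str, CompoundAnnotation]:
    annotations: dict[str, CompoundAnnotation] = {}
    for cid in compound_ids:
        target_class = CLASS_POOL[rng.integers(0, len(CLASS_POOL))]
        in_use = bool(rng.random() < 0.4)
        indication = (
            INDICATION_POOL[rng.integers(0, len(INDICATION_POOL))] if in_use else ""
        )
        annotations[cid] = CompoundAnnotation(
            compound_id=cid,
            name=f"compound-{cid}",
            clinical_indication=indication,
            in_clinical_use=in_use,
            pathway="",
            bbb_permeable=("yes", "no", "unknown")[rng.integers(0, 3)],
            target_class=target_class,
            prior_evidence=bool(rng.random() < 0.1),
        )
    return annotations


# ---------------------------------------------------------------------------
# FASTQ / reference simulation
# ---------------------------------------------------------------------------

def simulate_reference(
    n_mirnas: int = 50,
    seed: int = 0,
    length_range: tuple[int, int] = (18, 24),
) -> MiRNAReference:
    """Random mature-miRNA reference with unambiguous sequences.

    Sequences are rejected if they collide with an existing entry under
    the quantifier's 3' tolerance (equal after adding/removing up to two
    terminal bases), so exact-composition closure tests are well defined.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    entries: dict[str, str] = {}
    seqs: list[str] = []

    def collides(candidate: str) -> bool:
        for s in seqs:
            short, long_ = sorted((candidate, s), key=len)
            if long_.startswith(short) and len(long_) - len(short) <= 4:
                return True
        return False

    width = max(3, len(str(n_mirnas)))
    i = 0
    while len(entries) < n_mirnas:
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(bases[rng.integers(0, 4, length)])
        if collides(seq):
            continue
        i += 1
        entries[f"miR-{i:0{width}d}"] = seq
        seqs.append(seq)
    return MiRNAReference(entries)


def simulate_fastq(
    proportions: Mapping[str, float] | pd.Series,
    reference: MiRNAReference,
    n_reads: int,
    path=None,
    adapter: str = DEFAULT_ADAPTER,
    seed: int = 0,
    read_length: int = 50,
) -> tuple[list[str], pd.Series]:
    """Simulate error-free reads: lead base + mature sequence + adapter + filler.

    Returns the FASTQ records (as text lines) and the realized multinomial
    composition per miRNA; quantifying the output reproduces the
    composition exactly.  ``path`` optionally writes the FASTQ.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    props = pd.Series(proportions, dtype=float)
    unknown = [m for m in props.index if m not in reference.entries]
    if unknown:
        raise ValidationError(f"proportions reference unknown miRNAs: {unknown}")
    props = props / props.sum()
    rng = np.random.default_rng(seed)
    composition = pd.Series(
        rng.multinomial(n_reads, props.to_numpy()), index=props.index, name="reads"
    )
    bases = "ACGT"
    lines: list[str] = []
    read_no = 0
    for mid, count in composition.items():
        mature = reference.entries[mid]
        for _ in range(int(count)):
            read_no += 1
            lead = bases[rng.integers(0, 4)]
            seq = lead + mature + adapter
            while len(seq) < read_length:
                seq += bases[rng.integers(0, 4)]
            seq = seq[:read_length]
            lines += [f"@sim_read_{read_no} {mid}", seq, "+", "I" * len(seq)]
    if path is not None:
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    return lines, composition


# ---------------------------------------------------------------------------
# Dose-response / qPCR simulation
# ---------------------------------------------------------------------------

def simulate_dose_response(
    truth: Mapping[str, float],
    doses: Sequence[float],
    replicates: int = 6,
    noise_cv: float = 0.1,
    seed: int = 0,
    compound_id: str = "compound",
    dose_unit: str = "nM",
    path=None,
) -> pd.DataFrame:
    """Replicate 4PL responses with multiplicative log-normal noise.

    ``truth`` holds bottom/top/ec50/hill (ec50 in the units of ``doses``).
    response = 4PL(dose) * exp(N(0, log(1 + noise_cv))); noise 0 puts the
    responses exactly on the curve.
    """
    rng = np.random.default_rng(seed)
    sigma = np.log1p(noise_cv)
    rows = []
    for dose in doses:
        y = four_pl(dose, truth["bottom"], truth["top"], truth["ec50"], truth["hill"])
        for rep in range(1, replicates + 1):
            noise = np.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
            rows.append(
                {
                    "compound_id": compound_id,
                    "dose": float(dose),
                    "dose_unit": dose_unit,
                    "response": float(y * noise),
                    "replicate": rep,
                }
            )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False, lineterminator="\n")
    return df


def simulate_qpcr(
    true_folds: Mapping[str, float],
    reference_genes: Sequence[str] = ("miR-103a", "let-7a"),
    ct_noise_sd: float = 0.2,
    replicates: int = 4,
    seed: int = 0,
    base_ct: float = 25.0,
    reference_ct: float = 20.0,
    path=None,
) -> pd.DataFrame:
    """Simulate a long-format qPCR Ct table from known fold changes.

    Treated target Ct = control Ct - log2(fold) + noise; reference genes
    sit at a constant Ct + noise in every sample.  ``ct_noise_sd = 0``
    makes the planted ddCt exact.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for condition in ("control", "treated"):
        for rep in range(1, replicates + 1):
            sample = f"{condition}_{rep}"
            for gene, fold in true_folds.items():
                shift = -np.log2(fold) if condition == "treated" else 0.0
                ct = base_ct + shift + rng.normal(0.0, ct_noise_sd)
                rows.append(
                    {
                        "sample": sample,
                        "condition": condition,
                        "gene": gene,
                        "role": "target",
                        "ct": float(ct),
                    }
                )
            for gene in reference_genes:
                ct = reference_ct + rng.normal(0.0, ct_noise_sd)
                rows.append(
                    {
                        "sample": sample,
                        "condition": condition,
                        "gene": gene,
                        "role": "reference",
                        "ct": float(ct),
                    }
                )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False, lineterminator="\n")
    return df
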