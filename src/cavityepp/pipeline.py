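"""End-to-end orchestration and the label-encoded reference fixture.

``run_pipeline`` sequences the stages — QC, GRM, social pedigree,
parentage classification, sexing, spatiotemporal metrics, model battery —
on a simulated or loaded dataset, persisting every intermediate and
keeping a conservation ledger of record counts per stage.

``make_reference_fixture`` builds a small dataset whose *labels* (not
genotypes) encode a published two-species outcome: per-plot brood and
nestling counts, cuckolded fathers, half-sibling-evidence nests and a
single brood-parasitism case.  It exercises the summary and test layers
exactly, independent of the stochastic GRM layer.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import filter_call_rate, grm_gcta, write_grm_csv
from .parentage import (
    ClassificationThresholds,
    ParentageCallSet,
    classify_parentage,
    summarize_epp,
    summary_to_json,
)
from .sexing import assign_sex, find_sex_linked_loci
from .spatiotemporal import SPECIES_PARAMS, compute_metrics, derive_radii
from .stats import chi_square_2x2, run_model_battery
from .synthetic_data import SimulationConfig, simulate_population

__all__ = [
    "PipelineConfig",
    "RunReport",
    "run_pipeline",
    "make_reference_fixture",
    "epp_chi_square_battery",
]


@dataclasses.dataclass
class PipelineConfig:
    """Knobs for one end-to-end run on simulated data."""

    simulation: SimulationConfig = dataclasses.field(
        default_factory=SimulationConfig
    )
    thresholds: ClassificationThresholds = dataclasses.field(
        default_factory=ClassificationThresholds
    )
    call_rate_threshold: float = 0.70
    radii_override: tuple[float, ...] | None = None
    n_mc_splits: int = 50
    seed: int = 0
    output_dir: str | None = None


@dataclasses.dataclass
class RunReport:
    """Per-stage ledger plus the summary tables of one pipeline run."""

    stage_counts: dict
    epp_summary: pd.DataFrame
    radii: tuple[float, ...]
    metrics: pd.DataFrame
    sex_assignments: pd.DataFrame
    sex_cv_accuracy: float
    model_report: dict
    calls: ParentageCallSet
    warnings: list


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Simulate, classify and model one species' season; see module docs."""
    out = Path(config.output_dir) if config.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    ledger: dict = {}
    warns: list = []

    sim = simulate_population(config.simulation)
    genotypes, records, pedigree, truth = sim
    ledger["simulated"] = {
        "individuals": genotypes.n_individuals,
        "loci": genotypes.n_loci,
        "nests": len(records),
    }

    filtered, qc_report = filter_call_rate(genotypes, config.call_rate_threshold)
    ledger["qc"] = {
        "individuals_in": genotypes.n_individuals,
        "individuals_out": filtered.n_individuals,
        "individuals_removed": len(qc_report.removed_individuals),
        "loci_in": genotypes.n_loci,
        "loci_out": filtered.n_loci,
        "loci_removed": len(qc_report.removed_loci),
    }
    assert (
        ledger["qc"]["individuals_out"] + ledger["qc"]["individuals_removed"]
        == ledger["qc"]["individuals_in"]
    )

    grm = grm_gcta(filtered)
    if out:
        write_grm_csv(grm, out / "grm.csv")

    calls = classify_parentage(grm, pedigree, records, config.thresholds)
    ledger["parentage"] = {
        "father_offspring_pairs": len(calls.father_offspring),
        "ambiguous": int((calls.father_offspring["call"] == "ambiguous").sum()),
        "epf_links": int((~calls.epf_links["removed_as_sibling"]).sum()),
        "parasites": len(calls.parasites),
    }
    if out:
        calls.to_csv(out / "calls")
    summary = summarize_epp(calls, records)

    # sexing: train on adults of known sex, assign nestlings
    meta = filtered.metadata
    adult_ids = [i for i in filtered.ids if meta.at[i, "stage"] == "adult"]
    nestling_ids = [i for i in filtered.ids if meta.at[i, "stage"] == "nestling"]
    adults = filtered.subset(ids=adult_ids)
    nestlings = filtered.subset(ids=nestling_ids)
    known_sex = meta.loc[adult_ids, "sex"]
    panel = find_sex_linked_loci(adults, known_sex, seed=config.seed)
    if len(panel) == 0:
        warns.append("no sex-linked loci found; nestlings left unsexed")
        sex_assignments = pd.DataFrame(
            {"id": nestling_ids, "sex": "unknown", "posterior": np.nan}
        )
        cv_acc = float("nan")
    else:
        sex_assignments, cv_acc = assign_sex(
            panel, adults, known_sex, nestlings,
            n_mc_splits=config.n_mc_splits, seed=config.seed,
        )
    ledger["sexing"] = {
        "panel_size": len(panel),
        "nestlings_assigned": int((sex_assignments["sex"] != "unknown").sum()),
        "cv_accuracy": cv_acc,
    }
    if out:
        sex_assignments.to_csv(out / "sex_assignments.csv", index=False)

    species = config.simulation.species
    params = SPECIES_PARAMS[species]
    epf = calls.epf_links[~calls.epf_links["removed_as_sibling"]]
    if config.radii_override is not None:
        radii = tuple(config.radii_override)
    else:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            radii = derive_radii(
                epf, records, params.radius_multipliers,
                default_base=params.base_radius_m,
            )
            warns.extend(str(w.message) for w in caught)
    metrics = compute_metrics(records, radii, params)
    if out:
        metrics.to_csv(out / "spatiotemporal_metrics.csv", index=False)

    model_report = run_model_battery(calls, metrics, records, sim.offspring)
    ledger["models"] = model_report["filter_ledger"]

    if out:
        summary.to_csv(out / "epp_summary.csv", index=False)
        summary_to_json(summary, out / "epp_summary.json")

    return RunReport(
        stage_counts=ledger,
        epp_summary=summary,
        radii=radii,
        metrics=metrics,
        sex_assignments=sex_assignments,
        sex_cv_accuracy=cv_acc,
        model_report=model_report,
        calls=calls,
        warnings=warns,
    )


# ---------------------------------------------------------------------------
# label-encoded reference fixture
# ---------------------------------------------------------------------------

def _fixture_plot(
    rows_nests: list,
    rows_status: list,
    species: str,
    plot: str,
    n_father_nests: int,
    n_halfsib_nests: int,
    n_offspring: int,
    epo_per_nest: list[int],
    parasite_in_first_nest: bool = False,
) -> None:
    """Append one plot's nests/offspring with exact label counts.

    ``epo_per_nest`` gives the EPO count of each cuckolded-father nest; the
    remaining father-sampled nests are all-within-pair.  Offspring are
    spread as evenly as possible so every nest has a plausible brood.
    """
    base = n_offspring // n_father_nests
    extra = n_offspring - base * n_father_nests
    brood_sizes = [base + 1] * extra + [base] * (n_father_nests - extra)
    epo_counts = epo_per_nest + [0] * (n_father_nests - len(epo_per_nest))
    assert all(e < b for e, b in zip(epo_counts, brood_sizes)), (
        "a brood would be entirely extra-pair"
    )
    tag = f"{species[:2].upper()}{plot[:3].upper()}"
    for k in range(n_father_nests):
        nest_id = f"{tag}{k + 1:03d}"
        rows_nests.append(
            {
                "nest_id": nest_id,
                "species": species,
                "plot": plot,
                "cavity_type": plot,
                "source": "father_calls",
                "epp": epo_counts[k] > 0,
                "n_epo": epo_counts[k],
                "n_called": brood_sizes[k],
            }
        )
        for j in range(brood_sizes[k]):
            rows_status.append(
                {
                    "offspring": f"{nest_id}_o{j + 1}",
                    "nest_id": nest_id,
                    "status": "epo" if j < epo_counts[k] else "wpo",
                }
            )
        if parasite_in_first_nest and k == 0:
            rows_status.append(
                {
                    "offspring": f"{nest_id}_px",
                    "nest_id": nest_id,
                    "status": "parasite",
                }
            )
    for k in range(n_halfsib_nests):
        nest_id = f"{tag}H{k + 1:02d}"
        rows_nests.append(
            {
                "nest_id": nest_id,
                "species": species,
                "plot": plot,
                "cavity_type": plot,
                "source": "sibling_evidence",
                "epp": True,
                "n_epo": pd.NA,
                "n_called": 0,
            }
        )


def make_reference_fixture(directory=None) -> tuple[pd.DataFrame, ParentageCallSet]:
    """Label-encoded dataset reproducing a published two-species outcome.

    Blue tits: 30 natural-cavity broods (11 EPP-positive) and 37 nestbox
    broods (17), 197 + 237 nestlings with father calls of which 16 + 28 are
    extra-pair; great tits: 32 (12) and 26 (16) broods, 179 + 189 nestlings
    with 20 + 30 extra-pair.  Per species, EPP-positive broods decompose as
    25 cuckolded fathers + 3 half-sibling-evidence nests, and one blue tit
    nestling is a brood parasite.

    Returns ``(nest_records, calls)`` ready for :func:`summarize_epp` and
    the chi-square battery; writes CSVs when ``directory`` is given.
    """
    nests: list = []
    status: list = []
    # cuckolded-father nests per plot, with per-nest EPO counts summing to
    # the printed nestling-level numerators
    _fixture_plot(nests, status, "blue_tit", "natural", 29, 1, 197,
                  [2] * 6 + [1] * 4, parasite_in_first_nest=True)
    _fixture_plot(nests, status, "blue_tit", "nestbox", 35, 2, 237,
                  [2] * 13 + [1] * 2)
    _fixture_plot(nests, status, "great_tit", "natural", 31, 1, 179,
                  [2] * 9 + [1] * 2)
    _fixture_plot(nests, status, "great_tit", "nestbox", 24, 2, 189,
                  [3] * 2 + [2] * 12)
    nest_df = pd.DataFrame(nests)
    status_df = pd.DataFrame(status)

    records = nest_df[
        ["nest_id", "species", "plot", "cavity_type"]
    ].copy()
    records["year"] = 2018
    records["offspring_ids"] = [
        ";".join(status_df.loc[status_df["nest_id"] == nid, "offspring"])
        for nid in records["nest_id"]
    ]
    parasites = status_df[status_df["status"] == "parasite"].rename(
        columns={"offspring": "offspring"}
    )[["offspring", "nest_id"]].assign(max_grm_to_family=0.02)
    calls = ParentageCallSet(
        father_offspring=pd.DataFrame(
            columns=["offspring", "father", "grm", "call"]
        ),
        sibling_pairs=pd.DataFrame(
            columns=["id1", "id2", "nest_id", "grm", "call"]
        ),
        epf_links=pd.DataFrame(
            columns=["male", "offspring", "nest_id", "grm", "removed_as_sibling"]
        ),
        parasites=parasites,
        offspring_status=status_df,
        nest_epp=nest_df[
            ["nest_id", "source", "epp", "n_epo", "n_called"]
        ].copy(),
    )
    if directory is not None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        records.to_csv(d / "nest_records.csv", index=False)
        calls.to_csv(d / "calls")
    return records, calls


def epp_chi_square_battery(summary: pd.DataFrame) -> dict:
    """Cavity-type chi-square tests from a summarize_epp table.

    For each species: a brood-level test on (EPP-positive, EPP-negative)
    broods by plot and a nestling-level test on (EPO, within-pair) counts,
    both Yates-corrected.
    """
    out = {}
    for species, grp in summary.groupby("species"):
        grp = grp.set_index("plot")
        nat, box = grp.loc["natural"], grp.loc["nestbox"]
        out[(species, "broods")] = chi_square_2x2(
            int(nat["n_broods_epp"]),
            int(nat["n_broods"] - nat["n_broods_epp"]),
            int(box["n_broods_epp"]),
            int(box["n_broods"] - box["n_broods_epp"]),
        )
        out[(species, "nestlings")] = chi_square_2x2(
            int(nat["n_epo"]),
            int(nat["n_offspring"] - nat["n_epo"]),
            int(box["n_epo"]),
            int(box["n_offspring"] - box["n_epo"]),
        )
    return out
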