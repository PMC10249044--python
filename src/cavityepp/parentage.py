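"""Threshold-band parentage classification from GRM vs social pedigree.

Discrepancies between realized genomic relatedness (GRM) and the social
expectation reveal extra-pair paternity.  The classification bands:

* father-offspring pairs (social r = 0.5): GRM > 0.35 -> within-pair,
  GRM < 0.15 -> extra-pair offspring (EPO); the gap [0.15, 0.35] is left
  ambiguous (no printed rule covers it) and excluded from counts.
* adult male vs non-social offspring (social r = 0): GRM > 0.35 -> the male
  is that offspring's extra-pair father (EPF), after screening out males
  who are actually full siblings of the offspring from a previous cohort.
* within-brood sibling pairs: GRM in (0.15, 0.35) -> half-siblings (evidence
  of multiple sires), > 0.35 -> full siblings, < 0.15 -> flagged unrelated
  (feeds the brood-parasitism check).
* a nestling below 0.1 to every genotyped social parent AND all social
  siblings -> brood parasitism.

Thresholds are strict inequalities; boundary values fall into the ambiguous
or negative class.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import RelatednessMatrix
from .pedigree import SocialPedigree

__all__ = [
    "ClassificationThresholds",
    "ParentageCallSet",
    "classify_father_offspring",
    "find_extra_pair_fathers",
    "classify_sibling_pairs",
    "detect_brood_parasitism",
    "classify_parentage",
    "summarize_epp",
]


@dataclass(frozen=True)
class ClassificationThresholds:
    """GRM cut-offs for the relationship bands."""

    within_pair_min: float = 0.35
    extra_pair_max: float = 0.15
    halfsib_low: float = 0.15
    halfsib_high: float = 0.35
    parasite_max: float = 0.10
    epf_min: float = 0.35

    def __post_init__(self) -> None:
        if not (
            self.parasite_max <= self.extra_pair_max < self.within_pair_min
        ):
            raise ValueError(
                "need parasite_max <= extra_pair_max < within_pair_min"
            )


@dataclass
class ParentageCallSet:
    """All classification outputs for one species' dataset."""

    father_offspring: pd.DataFrame  # offspring, father, grm, call
    sibling_pairs: pd.DataFrame     # id1, id2, nest_id, grm, call
    epf_links: pd.DataFrame         # male, offspring, grm, removed_as_sibling
    parasites: pd.DataFrame         # offspring, nest_id, max_grm_to_family
    offspring_status: pd.DataFrame  # offspring, nest_id, status (wpo/epo/...)
    nest_epp: pd.DataFrame          # nest_id, epp, n_epo, n_called, source
    unclassifiable: list[str] = field(default_factory=list)

    def to_csv(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.father_offspring.to_csv(d / "father_offspring_calls.csv", index=False)
        self.sibling_pairs.to_csv(d / "sibling_pair_calls.csv", index=False)
        self.epf_links.to_csv(d / "epf_links.csv", index=False)
        self.parasites.to_csv(d / "parasite_calls.csv", index=False)
        self.offspring_status.to_csv(d / "offspring_status.csv", index=False)
        self.nest_epp.to_csv(d / "nest_epp.csv", index=False)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _grm_lookup(grm: RelatednessMatrix):
    idx = {i: r for r, i in enumerate(grm.ids)}

    def get(i: str, j: str) -> float:
        a, b = idx.get(i), idx.get(j)
        if a is None or b is None:
            return float("nan")
        return float(grm.values[a, b])

    return idx, get


def _offspring_of(records: pd.DataFrame) -> pd.DataFrame:
    """One row per offspring with nest/parent columns, from nest records."""
    rows = []
    for _, rec in records.iterrows():
        offs = rec.get("offspring_ids", [])
        if isinstance(offs, str):
            offs = [o for o in offs.split(";") if o]
        for o in offs:
            rows.append(
                {
                    "offspring": str(o),
                    "nest_id": str(rec["nest_id"]),
                    "mother": rec.get("mother_id"),
                    "father": rec.get("father_id"),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# classification operations
# ---------------------------------------------------------------------------

def classify_father_offspring(
    grm: RelatednessMatrix,
    pedigree: SocialPedigree,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> pd.DataFrame:
    """Classify every genotyped social father-offspring pair.

    Returns a frame with columns ``offspring, father, grm, call`` where call
    is ``within_pair`` (G > 0.35), ``extra_pair`` (G < 0.15) or
    ``ambiguous`` (the unprinted gap, reported but excluded from counts).
    Pairs whose father is not genotyped are skipped (the nest is handled by
    the sibling-evidence path).
    """
    idx, get = _grm_lookup(grm)
    rows = []
    for off in pedigree.ids:
        fa = pedigree.father_of(off)
        if fa is None or off not in idx or fa not in idx:
            continue
        g = get(off, fa)
        if np.isnan(g):
            continue
        if g > thresholds.within_pair_min:
            call = "within_pair"
        elif g < thresholds.extra_pair_max:
            call = "extra_pair"
        else:
            call = "ambiguous"
        rows.append({"offspring": off, "father": fa, "grm": g, "call": call})
    return pd.DataFrame(rows, columns=["offspring", "father", "grm", "call"])


def find_extra_pair_fathers(
    grm: RelatednessMatrix,
    pedigree: SocialPedigree,
    records: pd.DataFrame,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
    adult_males: list[str] | None = None,
) -> pd.DataFrame:
    """Identify extra-pair fathers among genotyped adult males.

    A link (male, offspring) is proposed when the social relatedness is 0
    (the male is not the offspring's social father and no pedigree path
    connects them) and GRM > 0.35.  Candidates where the pedigree shows the
    two are full siblings from a previous cohort are removed as false
    positives (``removed_as_sibling=True``) but kept in the frame for
    reporting.
    """
    from .pedigree import expected_relatedness

    idx, get = _grm_lookup(grm)
    off_tbl = _offspring_of(records)
    if adult_males is None:
        adult_males = sorted(
            {
                str(f)
                for f in records["father_id"].dropna()
                if str(f) in idx and str(f) != ""
            }
        )
    rows = []
    for _, orow in off_tbl.iterrows():
        off = orow["offspring"]
        if off not in idx:
            continue
        social_fa = orow["father"]
        for male in adult_males:
            if male == social_fa:
                continue
            g = get(male, off)
            if np.isnan(g) or g <= thresholds.epf_min:
                continue
            removed = _full_sibling_prior_cohort(pedigree, male, off)
            if not removed:
                social_r = (
                    expected_relatedness(pedigree, male, off)
                    if (male in pedigree and off in pedigree)
                    else 0.0
                )
                if social_r != 0.0:
                    continue  # pedigree explains the relatedness

            rows.append(
                {
                    "male": male,
                    "offspring": off,
                    "nest_id": orow["nest_id"],
                    "grm": g,
                    "removed_as_sibling": removed,
                }
            )
    return pd.DataFrame(
        rows, columns=["male", "offspring", "nest_id", "grm", "removed_as_sibling"]
    )


def _full_sibling_prior_cohort(
    ped: SocialPedigree, male: str, off: str
) -> bool:
    """Field-record screen: are the two full siblings from different years?"""
    if male not in ped or off not in ped:
        return False
    mm, mf = ped.mother_of(male), ped.father_of(male)
    om, of = ped.mother_of(off), ped.father_of(off)
    if None in (mm, mf, om, of):
        return False
    if (mm, mf) != (om, of):
        return False
    ym = ped.entries.at[male, "year"]
    yo = ped.entries.at[off, "year"]
    return pd.notna(ym) and pd.notna(yo) and ym != yo


def classify_sibling_pairs(
    grm: RelatednessMatrix,
    pedigree: SocialPedigree,
    records: pd.DataFrame,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> pd.DataFrame:
    """Classify within-nest sibling pairs (social r = 0.5).

    ``half`` for GRM in (0.15, 0.35), ``full`` above 0.35, and
    ``unrelated_flag`` below 0.15 (candidate parasite signal).  Singleton
    broods yield no pairs.
    """
    idx, get = _grm_lookup(grm)
    off_tbl = _offspring_of(records)
    rows = []
    for nest_id, grp in off_tbl.groupby("nest_id"):
        sibs = [o for o in grp["offspring"] if o in idx]
        for a in range(len(sibs)):
            for b in range(a + 1, len(sibs)):
                g = get(sibs[a], sibs[b])
                if np.isnan(g):
                    continue
                if g > thresholds.halfsib_high:
                    call = "full"
                elif g > thresholds.halfsib_low:
                    call = "half"
                else:
                    call = "unrelated_flag"
                rows.append(
                    {
                        "id1": sibs[a],
                        "id2": sibs[b],
                        "nest_id": nest_id,
                        "grm": g,
                        "call": call,
                    }
                )
    return pd.DataFrame(rows, columns=["id1", "id2", "nest_id", "grm", "call"])


def detect_brood_parasitism(
    grm: RelatednessMatrix,
    pedigree: SocialPedigree,
    records: pd.DataFrame,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> tuple[pd.DataFrame, list[str]]:
    """Nestlings below the parasite threshold to all genotyped relatives.

    An offspring is called a parasite when its GRM to *every* genotyped
    social parent and to *all* genotyped social siblings is < 0.1.
    Offspring with no genotyped relatives at all are unclassifiable and
    returned separately.
    """
    idx, get = _grm_lookup(grm)
    off_tbl = _offspring_of(records)
    rows = []
    unclassifiable = []
    for _, orow in off_tbl.iterrows():
        off = orow["offspring"]
        if off not in idx:
            continue
        relatives = []
        for parent in (orow["mother"], orow["father"]):
            if parent is not None and pd.notna(parent) and str(parent) in idx:
                relatives.append(str(parent))
        sibs = [
            s
            for s in off_tbl.loc[
                off_tbl["nest_id"] == orow["nest_id"], "offspring"
            ]
            if s != off and s in idx
        ]
        relatives.extend(sibs)
        gvals = [get(off, r) for r in relatives]
        gvals = [g for g in gvals if not np.isnan(g)]
        if not gvals:
            unclassifiable.append(off)
            continue
        if max(gvals) < thresholds.parasite_max:
            rows.append(
                {
                    "offspring": off,
                    "nest_id": orow["nest_id"],
                    "max_grm_to_family": max(gvals),
                }
            )
    return (
        pd.DataFrame(rows, columns=["offspring", "nest_id", "max_grm_to_family"]),
        unclassifiable,
    )


# ---------------------------------------------------------------------------
# full classification + summaries
# ---------------------------------------------------------------------------

def classify_parentage(
    grm: RelatednessMatrix,
    pedigree: SocialPedigree,
    records: pd.DataFrame,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> ParentageCallSet:
    """Run the full classification chain and assemble per-nest EPP calls.

    Nests with a genotyped social father get per-offspring EPO calls from
    the father-offspring bands; nests without one are routed to the
    sibling-evidence path, where the presence of half-sibling pairs marks
    the brood EPP-positive without identifying which nestling is extra-pair.
    """
    fo = classify_father_offspring(grm, pedigree, thresholds)
    sibs = classify_sibling_pairs(grm, pedigree, records, thresholds)
    epf = find_extra_pair_fathers(grm, pedigree, records, thresholds)
    parasites, unclassifiable = detect_brood_parasitism(
        grm, pedigree, records, thresholds
    )
    parasite_ids = set(parasites["offspring"])

    off_tbl = _offspring_of(records)
    idx = {i: r for r, i in enumerate(grm.ids)}
    fo_call = dict(zip(fo["offspring"], fo["call"]))
    status_rows = []
    for _, orow in off_tbl.iterrows():
        off = orow["offspring"]
        if off not in idx:
            status = "ungenotyped"
        elif off in parasite_ids:
            status = "parasite"
        elif off in fo_call:
            status = {
                "within_pair": "wpo",
                "extra_pair": "epo",
                "ambiguous": "ambiguous",
            }[fo_call[off]]
        else:
            status = "no_father_call"
        status_rows.append(
            {"offspring": off, "nest_id": orow["nest_id"], "status": status}
        )
    status = pd.DataFrame(status_rows)

    nest_rows = []
    for nest_id, grp in status.groupby("nest_id"):
        called = grp[grp["status"].isin(["wpo", "epo"])]
        n_epo = int((grp["status"] == "epo").sum())
        if len(called) > 0:
            nest_rows.append(
                {
                    "nest_id": nest_id,
                    "source": "father_calls",
                    "epp": n_epo > 0,
                    "n_epo": n_epo,
                    "n_called": len(called),
                }
            )
        else:
            nest_sibs = sibs[sibs["nest_id"] == nest_id]
            informative = nest_sibs[nest_sibs["call"].isin(["full", "half"])]
            if len(informative) == 0:
                nest_rows.append(
                    {
                        "nest_id": nest_id,
                        "source": "uninformative",
                        "epp": pd.NA,
                        "n_epo": pd.NA,
                        "n_called": 0,
                    }
                )
            else:
                has_half = bool((informative["call"] == "half").any())
                nest_rows.append(
                    {
                        "nest_id": nest_id,
                        "source": "sibling_evidence",
                        "epp": has_half,
                        "n_epo": pd.NA,
                        "n_called": 0,
                    }
                )
    nest_epp = pd.DataFrame(
        nest_rows, columns=["nest_id", "source", "epp", "n_epo", "n_called"]
    )
    return ParentageCallSet(
        father_offspring=fo,
        sibling_pairs=sibs,
        epf_links=epf,
        parasites=parasites,
        offspring_status=status,
        nest_epp=nest_epp,
        unclassifiable=unclassifiable,
    )


def summarize_epp(
    calls: ParentageCallSet, records: pd.DataFrame
) -> pd.DataFrame:
    """Per species x plot EPP summary at brood and offspring level.

    Brood level: broods with >=1 EPO (or half-sib evidence where the father
    was unsampled) over broods with paternity information.  Offspring
    level: EPO count over offspring with a definite father-pair call.
    Percentages are rounded to the nearest integer for report parity.
    """
    if len(calls.nest_epp) == 0:
        warnings.warn("empty call set; returning empty summary")
        return pd.DataFrame(
            columns=[
                "species", "plot", "n_broods", "n_broods_epp", "pct_broods_epp",
                "n_offspring", "n_epo", "pct_epo",
            ]
        )
    rec = records.set_index("nest_id")
    nest = calls.nest_epp.copy()
    nest["species"] = rec.loc[nest["nest_id"], "species"].to_numpy()
    plot_col = "cavity_type" if "cavity_type" in rec.columns else "plot"
    nest["plot"] = rec.loc[nest["nest_id"], plot_col].to_numpy()
    rows = []
    for (species, plot), grp in nest.groupby(["species", "plot"]):
        informative = grp[grp["source"] != "uninformative"]
        n_broods = len(informative)
        n_epp = int(sum(bool(v) for v in informative["epp"] if pd.notna(v)))
        fathered = grp[grp["source"] == "father_calls"]
        n_off = int(fathered["n_called"].sum())
        n_epo = int(pd.to_numeric(fathered["n_epo"], errors="coerce").fillna(0).sum())
        rows.append(
            {
                "species": species,
                "plot": plot,
                "n_broods": n_broods,
                "n_broods_epp": n_epp,
                "pct_broods_epp": int(round(100.0 * n_epp / n_broods))
                if n_broods else 0,
                "n_offspring": n_off,
                "n_epo": n_epo,
                "pct_epo": int(round(100.0 * n_epo / n_off)) if n_off else 0,
            }
        )
    return pd.DataFrame(rows)


def summary_to_json(summary: pd.DataFrame, path=None) -> str:
    """Nested counts + percentages per species x plot x level x class."""
    out: dict = {}
    for _, r in summary.iterrows():
        cell = out.setdefault(r["species"], {}).setdefault(r["plot"], {})
        cell["nest"] = {
            "EP": int(r["n_broods_epp"]),
            "WP": int(r["n_broods"] - r["n_broods_epp"]),
            "pct_EP": int(r["pct_broods_epp"]),
        }
        cell["offspring"] = {
            "EP": int(r["n_epo"]),
            "WP": int(r["n_offspring"] - r["n_epo"]),
            "pct_EP": int(r["pct_epo"]),
        }
    text = json.dumps(out, indent=2, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
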