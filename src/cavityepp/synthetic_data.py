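"""Synthetic breeding-population generator with known ground truth.

Emulates the data structure of a two-plot tit study: one plot of natural
cavities with irregular nest placement and one nestbox plot on a regular
50 m grid, socially monogamous pairs, Mendelian transmission of biallelic
SNPs from parents to nestlings, a controllable per-offspring extra-pair
rate with exponential distance decay in sire choice, occasional brood
parasitism, Z-linked loci under ZW sex determination, and per-genotype
missingness and symmetric allele-flip error.

Every downstream stage (QC, GRM, parentage classification, sexing,
spatiotemporal metrics, models) can be exercised against the returned
truth tables without any external download.

The generator simulates one species per call (the analyses run separately
per species); defaults approximate a mid-April laying season, clutches of
8-12 eggs and a ~10% extra-pair offspring rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .pedigree import SocialPedigree, build_pedigree

__all__ = [
    "PlotGeometry",
    "SimulationConfig",
    "TruthTables",
    "SimulatedPopulation",
    "simulate_population",
    "mendelian_check",
    "SPECIES_FERTILE_OFFSET",
]

#: Days before laying onset at which the female becomes fertile.
SPECIES_FERTILE_OFFSET = {"blue_tit": 2, "great_tit": 5}


@dataclass(frozen=True)
class PlotGeometry:
    """Axis-aligned rectangular plot in a local metric frame.

    ``spacing`` selects the nest-placement rule: ``"grid"`` places nests on
    a regular lattice with the given pitch plus uniform jitter (nestbox
    plots), ``"uniform"`` draws positions uniformly at random (natural
    cavities).
    """

    name: str
    cavity_type: str            # "natural" | "nestbox"
    x0: float
    y0: float
    width: float
    height: float
    spacing: str = "uniform"    # "uniform" | "grid"
    grid_pitch: float = 50.0
    grid_jitter: float = 5.0

    def overlaps(self, other: "PlotGeometry") -> bool:
        return not (
            self.x0 + self.width <= other.x0
            or other.x0 + other.width <= self.x0
            or self.y0 + self.height <= other.y0
            or other.y0 + other.height <= self.y0
        )


def _default_plots() -> tuple[PlotGeometry, PlotGeometry]:
    # natural plot ~50 ha irregular; nestbox plot ~15 ha on a 50 m grid,
    # separated by >200 m as in the study design
    return (
        PlotGeometry("natural", "natural", 0.0, 0.0, 700.0, 700.0, "uniform"),
        PlotGeometry("nestbox", "nestbox", 1000.0, 0.0, 400.0, 400.0, "grid"),
    )


@dataclass
class SimulationConfig:
    """Parameters of one synthetic breeding season.

    All probabilities are per-event; ``seed`` fixes every source of
    randomness end to end.
    """

    n_pairs_per_plot: int = 30
    plot_geometries: tuple[PlotGeometry, PlotGeometry] = field(
        default_factory=_default_plots
    )
    n_autosomal_loci: int = 5000
    n_sexlinked_loci: int = 20
    maf_min: float = 0.05                    # founder freqs ~ U(maf_min, 0.5)
    epp_rate: float = 0.10
    sire_decay_scale: float = 100.0          # metres
    parasitism_rate: float = 0.01
    unsampled_father_rate: float = 0.10
    missing_rate: float = 0.02
    error_rate: float = 0.005
    laying_mean: float = 108.0               # day of year
    laying_sd: float = 5.0
    clutch_min: int = 8
    clutch_max: int = 12
    species: str = "blue_tit"
    year: int = 2018
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "epp_rate",
            "parasitism_rate",
            "unsampled_father_rate",
            "missing_rate",
            "error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.maf_min < 0.5:
            raise ValueError("maf_min must be in (0, 0.5)")
        if self.n_pairs_per_plot < 2:
            raise ValueError("need at least 2 pairs per plot")
        a, b = self.plot_geometries
        if a.overlaps(b):
            raise ValueError("plot geometries overlap")
        if self.species not in SPECIES_FERTILE_OFFSET:
            raise ValueError(f"unknown species {self.species!r}")
        if self.clutch_min < 1 or self.clutch_max < self.clutch_min:
            raise ValueError("invalid clutch size range")


@dataclass
class TruthTables:
    """Ground-truth labels written by the simulator.

    ``offspring`` has one row per genotyped offspring: true sire id, EPO
    flag, parasite flag, true sex.  ``nests`` has the realized per-nest EPP
    occurrence and EPO proportion.  ``sex_linked_loci`` lists the loci on
    the Z chromosome.
    """

    offspring: pd.DataFrame
    nests: pd.DataFrame
    sex_linked_loci: list[str]
    true_mother: dict[str, str]
    true_father: dict[str, str]

    def __post_init__(self) -> None:
        if self.offspring.index.has_duplicates:
            raise ValueError("offspring appear more than once in truth table")
        bad = self.offspring[
            self.offspring["is_epo"]
            & (self.offspring["true_sire"] == self.offspring["social_father"])
        ]
        if len(bad):
            raise ValueError("EPO flags inconsistent with sire ids")

    def relatedness_class(self, i: str, j: str) -> str:
        """True pairwise class from the genetic (not social) parent maps."""
        mi, fi = self.true_mother.get(i), self.true_father.get(i)
        mj, fj = self.true_mother.get(j), self.true_father.get(j)
        if i in (mj, fj) or j in (mi, fi):
            return "parent_offspring"
        shared = int(mi is not None and mi == mj) + int(fi is not None and fi == fj)
        if shared == 2:
            return "full_sib"
        if shared == 1:
            return "half_sib"
        return "unrelated"


@dataclass
class SimulatedPopulation:
    """Bundle returned by :func:`simulate_population`."""

    genotypes: GenotypeMatrix
    nests: pd.DataFrame       # one row per nest
    offspring: pd.DataFrame   # one row per nestling (fledge status, measures)
    pedigree: SocialPedigree
    truth: TruthTables
    config: SimulationConfig

    def __iter__(self):
        # allow tuple unpacking (genotypes, nests, pedigree, truth)
        return iter((self.genotypes, self.nests, self.pedigree, self.truth))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _place_nests(rng, geom: PlotGeometry, n: int) -> np.ndarray:
    if geom.spacing == "grid":
        pitch = geom.grid_pitch
        nx = max(1, int(geom.width // pitch))
        ny = max(1, int(geom.height // pitch))
        if nx * ny < n:
            raise ValueError(
                f"plot {geom.name}: grid of {nx * ny} positions < {n} nests"
            )
        cells = rng.choice(nx * ny, size=n, replace=False)
        gx = geom.x0 + (cells % nx) * pitch + pitch / 2
        gy = geom.y0 + (cells // nx) * pitch + pitch / 2
        jit = rng.uniform(-geom.grid_jitter, geom.grid_jitter, size=(n, 2))
        return np.column_stack([gx, gy]) + jit
    xy = rng.uniform(0, 1, size=(n, 2))
    xy[:, 0] = geom.x0 + xy[:, 0] * geom.width
    xy[:, 1] = geom.y0 + xy[:, 1] * geom.height
    return xy


def _founder_genotypes(rng, n: int, p: np.ndarray) -> np.ndarray:
    """Diploid autosomal founders in Hardy-Weinberg proportions."""
    return (
        (rng.uniform(size=(n, p.size)) < p).astype(float)
        + (rng.uniform(size=(n, p.size)) < p).astype(float)
    )


def simulate_population(config: SimulationConfig) -> SimulatedPopulation:
    """Simulate one species' breeding season on two plots.

    Returns a :class:`SimulatedPopulation`; iterating over it yields
    ``(genotypes, nests, pedigree, truth)``.
    """
    rng = np.random.default_rng(config.seed)
    n_aut, n_z = config.n_autosomal_loci, config.n_sexlinked_loci
    aut_loci = [f"SNP{i:05d}" for i in range(n_aut)]
    z_loci = [f"ZSNP{i:03d}" for i in range(n_z)]
    p_aut = rng.uniform(config.maf_min, 0.5, size=n_aut)
    p_z = rng.uniform(config.maf_min, 0.5, size=n_z)

    # --- adults -----------------------------------------------------------
    nests = []
    adults: dict[str, dict] = {}
    aut: dict[str, np.ndarray] = {}      # autosomal dosage rows
    z_alleles: dict[str, np.ndarray] = {}  # (2, n_z) for males, (1, n_z) females
    nest_xy: dict[str, np.ndarray] = {}

    for geom in config.plot_geometries:
        xy = _place_nests(rng, geom, config.n_pairs_per_plot)
        for k in range(config.n_pairs_per_plot):
            nest_id = f"{geom.name[:3].upper()}{k + 1:03d}"
            mid, fid = f"F_{nest_id}", f"M_{nest_id}"
            for aid, sex in ((mid, "F"), (fid, "M")):
                adults[aid] = {"sex": sex, "plot": geom.name}
                aut[aid] = _founder_genotypes(rng, 1, p_aut)[0]
                n_all = 2 if sex == "M" else 1
                z_alleles[aid] = (
                    rng.uniform(size=(n_all, n_z)) < p_z
                ).astype(float)
            nest_xy[nest_id] = xy[k]
            laying = int(round(rng.normal(config.laying_mean, config.laying_sd)))
            clutch = int(rng.integers(config.clutch_min, config.clutch_max + 1))
            nests.append(
                {
                    "nest_id": nest_id,
                    "species": config.species,
                    "plot": geom.name,
                    "cavity_type": geom.cavity_type,
                    "year": config.year,
                    "x": xy[k, 0],
                    "y": xy[k, 1],
                    "laying_date": laying,
                    "clutch_size": clutch,
                    "mother_id": mid,
                    "father_id": fid,
                    "first_clutch": True,
                }
            )
    nests_df = pd.DataFrame(nests)

    # --- offspring --------------------------------------------------------
    males_by_plot = {
        g.name: [a for a, meta in adults.items() if meta["sex"] == "M"
                 and meta["plot"] == g.name]
        for g in config.plot_geometries
    }
    offspring_rows = []
    truth_rows = []
    off_aut: dict[str, np.ndarray] = {}
    off_z: dict[str, np.ndarray] = {}
    parasite_counter = 0

    def mate_autosomal(mo: str, fa_row: np.ndarray) -> np.ndarray:
        # one allele per parent per locus, uniform among the parent's two,
        # i.e. P(transmit alt) = dosage / 2
        gm = aut[mo]
        ma = (rng.uniform(size=n_aut) < gm / 2.0).astype(float)
        pa = (rng.uniform(size=n_aut) < fa_row / 2.0).astype(float)
        return ma + pa

    for _, nest in nests_df.iterrows():
        nest_id = nest["nest_id"]
        plot = nest["plot"]
        mo, fa = nest["mother_id"], nest["father_id"]
        parasitized = rng.uniform() < config.parasitism_rate
        parasite_slot = (
            int(rng.integers(nest["clutch_size"])) if parasitized else -1
        )
        # candidate extra-pair sires: same-plot males other than the social
        # father, weighted by exp(-d / scale)
        cand = [m for m in males_by_plot[plot] if m != fa]
        if not cand:
            raise ValueError(f"nest {nest_id}: no candidate extra-pair sires")
        cand_nest = [m.split("_", 1)[1] for m in cand]
        d = np.array(
            [np.linalg.norm(nest_xy[nest_id] - nest_xy[cn]) for cn in cand_nest]
        )
        w = np.exp(-d / config.sire_decay_scale)
        w /= w.sum()

        for slot in range(int(nest["clutch_size"])):
            oid = f"{nest_id}_o{slot + 1}"
            sex = "M" if rng.uniform() < 0.5 else "F"
            if slot == parasite_slot:
                # one implanted egg from an unrelated, unsampled pair
                parasite_counter += 1
                pm = f"PARA_F{parasite_counter}"
                pf = f"PARA_M{parasite_counter}"
                aut_m = _founder_genotypes(rng, 1, p_aut)[0]
                aut_f = _founder_genotypes(rng, 1, p_aut)[0]
                zm = (rng.uniform(size=(1, n_z)) < p_z).astype(float)
                zf = (rng.uniform(size=(2, n_z)) < p_z).astype(float)
                ma = (rng.uniform(size=n_aut) < aut_m / 2.0).astype(float)
                pa = (rng.uniform(size=n_aut) < aut_f / 2.0).astype(float)
                off_aut[oid] = ma + pa
                sire, true_mo, is_epo, is_para = pf, pm, False, True
                z_mother, z_father = zm, zf
            else:
                is_para = False
                true_mo = mo
                is_epo = rng.uniform() < config.epp_rate
                sire = cand[rng.choice(len(cand), p=w)] if is_epo else fa
                off_aut[oid] = mate_autosomal(mo, aut[sire])
                z_mother, z_father = z_alleles[mo], z_alleles[sire]
            # Z transmission: sons get mother's Z + one paternal Z;
            # daughters get one paternal Z only (hemizygous, coded 0/2)
            pat = z_father[rng.integers(2, size=n_z), np.arange(n_z)]
            if sex == "M":
                off_z[oid] = z_mother[0] + pat
            else:
                off_z[oid] = 2.0 * pat
            fledged = bool(rng.uniform() < 0.9)
            tarsus = rng.normal(16.5, 0.5)
            mass = np.exp(
                np.log(11.0) + 2.0 * (np.log(tarsus) - np.log(16.5))
                + rng.normal(0, 0.05)
            )
            offspring_rows.append(
                {
                    "id": oid,
                    "nest_id": nest_id,
                    "species": config.species,
                    "plot": plot,
                    "cavity_type": nest["cavity_type"],
                    "year": nest["year"],
                    "sex": sex,
                    "fledged": fledged,
                    "mass": mass,
                    "tarsus": tarsus,
                }
            )
            truth_rows.append(
                {
                    "id": oid,
                    "nest_id": nest_id,
                    "social_father": fa,
                    "social_mother": mo,
                    "true_sire": sire,
                    "true_mother": true_mo,
                    "is_epo": is_epo,
                    "is_parasite": is_para,
                    "sex": sex,
                }
            )

    offspring_df = pd.DataFrame(offspring_rows).set_index("id")
    truth_off = pd.DataFrame(truth_rows).set_index("id")

    # --- social pedigree and father sampling ------------------------------
    nests_df["offspring_ids"] = [
        ";".join(offspring_df.index[offspring_df["nest_id"] == nid])
        for nid in nests_df["nest_id"]
    ]
    unsampled_fathers = {
        row["father_id"]
        for _, row in nests_df.iterrows()
        if rng.uniform() < config.unsampled_father_rate
    }
    nests_df["father_sampled"] = ~nests_df["father_id"].isin(unsampled_fathers)
    pedigree = build_pedigree(nests_df)

    # --- assemble genotype matrix ----------------------------------------
    sampled_adults = [a for a in adults if a not in unsampled_fathers]
    ids = sampled_adults + list(offspring_df.index)
    loci = aut_loci + z_loci
    n_ind = len(ids)
    dos = np.empty((n_ind, n_aut + n_z))
    for r, ind in enumerate(ids):
        if ind in aut:
            dos[r, :n_aut] = aut[ind]
            za = z_alleles[ind]
            dos[r, n_aut:] = za.sum(axis=0) if za.shape[0] == 2 else 2.0 * za[0]
        else:
            dos[r, :n_aut] = off_aut[ind]
            dos[r, n_aut:] = off_z[ind]

    # error then missingness, applied last.  Symmetric allele-flip channel:
    # each physical allele flips independently with prob error_rate, so a
    # diploid genotype has two flip opportunities and a hemizygous Z female
    # one (her dosage jumps 0 <-> 2).
    if config.error_rate > 0:
        hemi = np.zeros((n_ind, n_aut + n_z), dtype=bool)
        sex_of = {**{a: adults[a]["sex"] for a in sampled_adults},
                  **truth_off["sex"].to_dict()}
        female = np.array([sex_of[i] == "F" for i in ids])
        hemi[np.ix_(female, np.arange(n_aut, n_aut + n_z))] = True
        flip1 = rng.uniform(size=dos.shape) < config.error_rate
        flip2 = rng.uniform(size=dos.shape) < config.error_rate
        a1 = (dos >= 1).astype(float)
        a2 = (dos == 2).astype(float)
        diploid = np.abs(a1 - flip1) + np.abs(a2 - flip2)
        hemizygous = np.where(flip1, 2.0 - dos, dos)
        dos = np.where(hemi, hemizygous, diploid)
    if config.missing_rate > 0:
        dos[rng.uniform(size=dos.shape) < config.missing_rate] = np.nan

    meta = pd.DataFrame(
        {
            "species": config.species,
            "plot": [
                adults[i]["plot"] if i in adults else offspring_df.at[i, "plot"]
                for i in ids
            ],
            "year": config.year,
            "stage": ["adult" if i in adults else "nestling" for i in ids],
            "sex": [
                adults[i]["sex"] if i in adults else None for i in ids
            ],
        },
        index=pd.Index(ids, name="id"),
    )
    genotypes = GenotypeMatrix(ids=ids, loci=loci, dosages=dos, metadata=meta)

    # --- per-nest truth ---------------------------------------------------
    nest_truth = (
        truth_off.groupby("nest_id")
        .agg(
            n_offspring=("is_epo", "size"),
            n_epo=("is_epo", "sum"),
            any_parasite=("is_parasite", "any"),
        )
        .assign(
            epp=lambda d: d["n_epo"] > 0,
            epo_proportion=lambda d: d["n_epo"] / d["n_offspring"],
        )
    )

    truth = TruthTables(
        offspring=truth_off,
        nests=nest_truth,
        sex_linked_loci=z_loci,
        true_mother=truth_off["true_mother"].to_dict(),
        true_father=truth_off["true_sire"].to_dict(),
    )
    return SimulatedPopulation(
        genotypes=genotypes,
        nests=nests_df,
        offspring=offspring_df,
        pedigree=pedigree,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# Mendelian-transmission oracle
# ---------------------------------------------------------------------------

#: offspring dosages compatible with (mother, father) dosages
_COMPAT: dict[tuple[int, int], set[int]] = {}
for _gm in range(3):
    for _gf in range(3):
        _ma = {0: {0}, 1: {0, 1}, 2: {1}}[_gm]
        _pa = {0: {0}, 1: {0, 1}, 2: {1}}[_gf]
        _COMPAT[(_gm, _gf)] = {a + b for a in _ma for b in _pa}


def mendelian_check(
    genotypes: GenotypeMatrix,
    pedigree: SocialPedigree,
    loci: list[str] | None = None,
) -> tuple[float, pd.DataFrame, int]:
    """Fraction of trio-locus combinations violating Mendelian transmission.

    Only trios with both parents genotyped are scored; trios with a member
    absent from the matrix are skipped and counted in the returned warning
    count.  The rate is ~0 for error-free data without extra-pair paternity
    and rises for trios whose recorded father is not the genetic sire.

    Returns ``(overall_rate, per_trio_frame, n_skipped)``.
    """
    if loci is None:
        loci = list(genotypes.loci)
    col = {l: j for j, l in enumerate(genotypes.loci)}
    cidx = np.array([col[l] for l in loci])
    row = {i: r for r, i in enumerate(genotypes.ids)}
    records = []
    n_skipped = 0
    for off in pedigree.ids:
        mo, fa = pedigree.mother_of(off), pedigree.father_of(off)
        if mo is None and fa is None:
            continue
        if off not in row or (mo is not None and mo not in row) or (
            fa is not None and fa not in row
        ):
            n_skipped += 1
            continue
        if mo is None or fa is None:
            n_skipped += 1
            continue
        go = genotypes.dosages[row[off], cidx]
        gm = genotypes.dosages[row[mo], cidx]
        gf = genotypes.dosages[row[fa], cidx]
        called = ~(np.isnan(go) | np.isnan(gm) | np.isnan(gf))
        n_called = int(called.sum())
        if n_called == 0:
            n_skipped += 1
            continue
        bad = 0
        for a, b, c in zip(gm[called], gf[called], go[called]):
            if int(c) not in _COMPAT[(int(a), int(b))]:
                bad += 1
        records.append(
            {
                "offspring": off,
                "mother": mo,
                "father": fa,
                "n_loci": n_called,
                "n_incompatible": bad,
                "rate": bad / n_called,
            }
        )
    if n_skipped:
        warnings.warn(f"mendelian_check: skipped {n_skipped} incomplete trios")
    per_trio = pd.DataFrame(records)
    if len(per_trio):
        overall = float(
            per_trio["n_incompatible"].sum() / per_trio["n_loci"].sum()
        )
    else:
        overall = float("nan")
    return overall, per_trio, n_skipped


def write_config(config: SimulationConfig, path) -> None:
    """Flat key=value dump of the scalar config fields."""
    with open(path, "w") as fh:
        for k, v in asdict(config).items():
            if k == "plot_geometries":
                for g in config.plot_geometries:
                    fh.write(
                        f"plot.{g.name}={g.cavity_type},{g.x0},{g.y0},"
                        f"{g.width},{g.height},{g.spacing}\n"
                    )
            else:
                fh.write(f"{k}={v}\n")
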