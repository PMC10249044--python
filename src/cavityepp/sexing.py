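"""Sex-linked SNP discovery and molecular sexing of nestlings.

Birds have ZW sex determination: males are ZZ (two Z alleles) and females
ZW (one Z allele).  Diploid genotype callers emit hemizygous female Z loci
as homozygous calls, so Z-linked SNPs show a striking heterozygosity
asymmetry (females never heterozygous) and a strong heterozygote deficit
relative to the pooled sample.  Discovery screens every locus for (a) a sex
difference in observed heterozygosity and (b) a high fixation index between
known-sex adults, with a label-permutation p-value per panel locus.  Nestlings are then assigned with a per-sex genotype-frequency naive
Bayes classifier over the panel loci; accuracy is reported from Monte-Carlo
cross-validation (random 70/30 splits of the known-sex adults).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "SexMarkerPanel",
    "find_sex_linked_loci",
    "SexClassifier",
    "assign_sex",
]


@dataclass
class SexMarkerPanel:
    """Loci selected as sex-linked, with the statistics that selected them."""

    table: pd.DataFrame  # locus, het_M, het_F, fst, perm_p
    het_diff_min: float
    fst_quantile: float

    @property
    def loci(self) -> list[str]:
        return list(self.table["locus"])

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _het_by_sex(dos: np.ndarray, is_m: np.ndarray, is_f: np.ndarray):
    het = dos == 1.0
    called = ~np.isnan(dos)
    with np.errstate(invalid="ignore"):
        het_m = het[is_m].sum(axis=0) / np.maximum(called[is_m].sum(axis=0), 1)
        het_f = het[is_f].sum(axis=0) / np.maximum(called[is_f].sum(axis=0), 1)
    return het_m, het_f


def _wc_fst(dos: np.ndarray, is_m: np.ndarray, is_f: np.ndarray) -> np.ndarray:
    """Per-locus fixation index of the two sexes against the pooled sample.

    Wright's F = 1 - H_obs / H_exp, with H_obs the sample-size-weighted
    observed heterozygosity within each sex and H_exp = 2 p (1 - p) from
    the pooled allele frequency.  A pure allele-frequency differentiation
    estimator (Weir-Cockerham theta) is blind to Z linkage under the
    hemizygous-as-homozygous coding convention: the sexes then share allele
    frequencies exactly and the signal is entirely a heterozygote deficit,
    which this index captures (F ~ 0.5 at a Z-linked locus, ~0 at an
    autosomal locus in Hardy-Weinberg proportions).
    """
    groups = [is_m, is_f]
    n_i = np.stack(
        [(~np.isnan(dos[g])).sum(axis=0) for g in groups]
    ).astype(float)
    h_i = np.stack(
        [
            (dos[g] == 1.0).sum(axis=0)
            / np.maximum((~np.isnan(dos[g])).sum(axis=0), 1)
            for g in groups
        ]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        n_tot = n_i.sum(axis=0)
        p_bar = np.nansum(dos[is_m | is_f], axis=0) / np.maximum(2.0 * n_tot, 1.0)
        h_obs = (n_i * h_i).sum(axis=0) / np.maximum(n_tot, 1.0)
        h_exp = 2.0 * p_bar * (1.0 - p_bar)
        f = np.where(h_exp > 0, 1.0 - h_obs / np.maximum(h_exp, 1e-300), 0.0)
    return np.clip(np.where(np.isfinite(f), f, 0.0), -1.0, 1.0)


def find_sex_linked_loci(
    adults: GenotypeMatrix,
    known_sex: pd.Series | dict,
    het_diff_min: float = 0.2,
    fst_quantile: float = 0.99,
    n_permutations: int = 999,
    seed: int = 0,
) -> SexMarkerPanel:
    """Screen loci for sex linkage in known-sex adults.

    Selects loci with ``|het_M - het_F| >= het_diff_min`` AND a
    sex-vs-pooled fixation index above the ``fst_quantile`` of its
    empirical per-locus distribution.  For each selected locus a
    permutation p-value is computed by shuffling sex labels
    (``n_permutations`` times) and asking how often the permuted
    heterozygosity difference reaches the observed value.
    """
    sex = pd.Series(known_sex).reindex(adults.ids)
    is_m = (sex == "M").to_numpy()
    is_f = (sex == "F").to_numpy()
    if is_m.sum() < 5 or is_f.sum() < 5:
        raise ValueError("need at least 5 known-sex adults per sex")
    dos = adults.dosages
    het_m, het_f = _het_by_sex(dos, is_m, is_f)
    fst = _wc_fst(dos, is_m, is_f)
    p_all = np.nansum(dos, axis=0) / (2.0 * np.maximum((~np.isnan(dos)).sum(axis=0), 1))
    poly = (p_all > 0) & (p_all < 1)
    if not poly.any():
        warnings.warn("all loci monomorphic; empty sex-marker panel")
        return SexMarkerPanel(
            pd.DataFrame(columns=["locus", "het_M", "het_F", "fst", "perm_p"]),
            het_diff_min,
            fst_quantile,
        )
    cut = np.quantile(fst[poly], fst_quantile)
    selected = poly & (np.abs(het_m - het_f) >= het_diff_min) & (fst > cut)

    # permutation p-value per panel locus on the (label-sensitive)
    # heterozygosity difference; the fixation index is invariant under
    # label shuffles so it cannot serve as the permuted statistic
    rng = np.random.default_rng(seed)
    labels = np.where(is_m, 1, np.where(is_f, 0, -1))
    usable = labels >= 0
    perm_p = np.full(dos.shape[1], np.nan)
    if selected.any() and n_permutations > 0:
        sel_idx = np.where(selected)[0]
        dsel = dos[usable][:, sel_idx]
        lab = labels[usable]
        observed = np.abs(het_m - het_f)[sel_idx]
        count = np.ones(len(sel_idx))  # +1 for the observed arrangement
        for _ in range(n_permutations):
            perm = rng.permutation(lab)
            hm, hf = _het_by_sex(dsel, perm == 1, perm == 0)
            count += np.abs(hm - hf) >= observed
        perm_p[sel_idx] = count / (n_permutations + 1)

    table = pd.DataFrame(
        {
            "locus": np.array(adults.loci)[selected],
            "het_M": het_m[selected],
            "het_F": het_f[selected],
            "fst": fst[selected],
            "perm_p": perm_p[selected],
        }
    ).reset_index(drop=True)
    return SexMarkerPanel(table, het_diff_min, fst_quantile)


class SexClassifier:
    """Per-sex genotype-frequency naive Bayes over a marker panel.

    For each panel locus and each sex, the frequency of genotype classes
    {0, 1, 2} is estimated from the training adults with add-one smoothing.
    A bird's posterior is the product of its genotype likelihoods under each
    sex (missing loci skipped), with a flat prior.
    """

    def __init__(self, panel_loci: list[str]):
        self.panel_loci = list(panel_loci)
        self._logp: dict[str, np.ndarray] = {}

    def fit(self, training: GenotypeMatrix, known_sex) -> "SexClassifier":
        sex = pd.Series(known_sex).reindex(training.ids)
        cidx = [training.loci.index(l) for l in self.panel_loci]
        dos = training.dosages[:, cidx]
        for label in ("M", "F"):
            rows = (sex == label).to_numpy()
            counts = np.ones((len(cidx), 3))  # add-one smoothing
            sub = dos[rows]
            for gval in (0, 1, 2):
                counts[:, gval] += np.nansum(sub == float(gval), axis=0)
            self._logp[label] = np.log(counts / counts.sum(axis=1, keepdims=True))
        return self

    def posterior_male(self, dosage_row: np.ndarray) -> float:
        called = ~np.isnan(dosage_row)
        if not called.any():
            return float("nan")
        idx = dosage_row[called].astype(int)
        pos = np.where(called)[0]
        lm = self._logp["M"][pos, idx].sum()
        lf = self._logp["F"][pos, idx].sum()
        m = max(lm, lf)
        return float(np.exp(lm - m) / (np.exp(lm - m) + np.exp(lf - m)))

    def predict(self, g: GenotypeMatrix) -> pd.DataFrame:
        cidx = [g.loci.index(l) for l in self.panel_loci]
        dos = g.dosages[:, cidx]
        rows = []
        for i, ind in enumerate(g.ids):
            pm = self.posterior_male(dos[i])
            if np.isnan(pm):
                rows.append({"id": ind, "sex": "unknown", "posterior": np.nan})
            else:
                sex = "M" if pm > 0.5 else "F"
                rows.append(
                    {"id": ind, "sex": sex, "posterior": max(pm, 1.0 - pm)}
                )
        return pd.DataFrame(rows)


def assign_sex(
    panel: SexMarkerPanel,
    training_adults: GenotypeMatrix,
    known_sex,
    nestlings: GenotypeMatrix,
    n_mc_splits: int = 100,
    test_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Assign sex to nestlings; report Monte-Carlo cross-validation accuracy.

    ``n_mc_splits`` random 70/30 train/test splits of the known-sex adults
    estimate the assignment accuracy; the final classifier is trained on all
    adults.  Nestlings missing every panel locus are returned as
    ``sex="unknown"``.
    """
    if len(panel) == 0:
        raise ValueError("empty sex-marker panel")
    sex = pd.Series(known_sex).reindex(training_adults.ids)
    rng = np.random.default_rng(seed)
    n = training_adults.n_individuals
    accs = []
    labels = sex.to_numpy()
    for _ in range(n_mc_splits):
        test_idx = rng.choice(n, size=max(1, int(round(test_fraction * n))),
                              replace=False)
        test_mask = np.zeros(n, dtype=bool)
        test_mask[test_idx] = True
        # splits must keep both sexes in training
        if len(set(labels[~test_mask])) < 2:
            continue
        train = training_adults.subset(
            ids=list(np.array(training_adults.ids)[~test_mask])
        )
        test = training_adults.subset(
            ids=list(np.array(training_adults.ids)[test_mask])
        )
        clf = SexClassifier(panel.loci).fit(train, sex[~test_mask])
        pred = clf.predict(test)
        truth = sex[test_mask].to_numpy()
        ok = pred["sex"].to_numpy() == truth
        known = pred["sex"].to_numpy() != "unknown"
        if known.any():
            accs.append(ok[known].mean())
    cv_accuracy = float(np.mean(accs)) if accs else float("nan")
    clf = SexClassifier(panel.loci).fit(training_adults, sex)
    assignments = clf.predict(nestlings)
    return assignments, cv_accuracy
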