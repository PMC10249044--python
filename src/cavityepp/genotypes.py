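"""Genotype containers, call-rate QC, and the GCTA genomic relatedness matrix.

Genotypes are biallelic SNPs coded as allele dosage (0/1/2 copies of the
alternate allele) with missing calls stored as NaN.  Relatedness between
individuals j and k is estimated with the GCTA single-SNP estimator

    G_jk = (1/m_jk) * sum_i (x_ji - 2 p_i)(x_ki - 2 p_i) / (2 p_i (1 - p_i))

summed over the m_jk loci observed in both individuals, and for the diagonal

    G_jj = 1 + (1/m_j) * sum_i (x_ji^2 - (1 + 2 p_i) x_ji + 2 p_i^2)
                               / (2 p_i (1 - p_i))

with p_i the sample alternate-allele frequency at locus i.  Missing data are
handled with pairwise-complete locus sets (no imputation), matching the
behaviour of the common GDS-based implementations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "RelatednessMatrix",
    "CallRateReport",
    "filter_call_rate",
    "allele_frequencies",
    "grm_gcta",
    "read_dosage_csv",
    "write_dosage_csv",
    "read_vcf",
    "write_vcf",
    "write_grm_csv",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Individuals x loci allele-dosage matrix with per-individual metadata.

    Parameters
    ----------
    ids
        Individual identifiers (unique, length n).
    loci
        Locus identifiers (unique, length m).
    dosages
        ``(n, m)`` float array with values in {0, 1, 2} and NaN for missing.
    metadata
        Optional per-individual table indexed by id.  Recognised columns:
        ``species``, ``plot``, ``year``, ``stage`` ("adult"/"nestling"),
        ``sex`` ("M"/"F"/NaN).
    """

    ids: list[str]
    loci: list[str]
    dosages: np.ndarray
    metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.loci = [str(l) for l in self.loci]
        self.dosages = np.asarray(self.dosages, dtype=float)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate individual ids")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate locus ids")
        if self.dosages.shape != (len(self.ids), len(self.loci)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.ids)} ids x {len(self.loci)} loci"
            )
        if len(self.ids) < 2 or len(self.loci) < 2:
            raise ValueError("need at least 2 individuals and 2 loci")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.unique(self.dosages[~ok])
            raise ValueError(f"dosages outside {{0,1,2,NaN}}: {bad[:5]}")
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=pd.Index(self.ids, name="id"))
        else:
            self.metadata = self.metadata.loc[self.ids]

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def subset(self, ids=None, loci=None) -> "GenotypeMatrix":
        """Return a copy restricted to the given individuals and/or loci."""
        row_ids = list(ids) if ids is not None else list(self.ids)
        col_ids = list(loci) if loci is not None else list(self.loci)
        ridx = [self.ids.index(i) for i in row_ids]
        cidx = [self.loci.index(l) for l in col_ids]
        return GenotypeMatrix(
            ids=row_ids,
            loci=col_ids,
            dosages=self.dosages[np.ix_(ridx, cidx)].copy(),
            metadata=self.metadata.loc[row_ids].copy(),
        )

    def call_rate_individuals(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def call_rate_loci(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)


@dataclass
class RelatednessMatrix:
    """Symmetric pairwise genomic relatedness with per-pair locus counts."""

    ids: list[str]
    values: np.ndarray       # (n, n) float, NaN where no shared loci
    n_loci_pair: np.ndarray  # (n, n) int, loci used per pair

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n) or self.n_loci_pair.shape != (n, n):
            raise ValueError("matrix shapes do not match id count")
        finite = ~np.isnan(self.values)
        sym = finite & finite.T
        if not np.allclose(
            self.values[sym], self.values.T[sym], atol=1e-12, rtol=0.0
        ):
            raise ValueError("relatedness matrix not symmetric within 1e-12")

    def get(self, i: str, j: str) -> float:
        return float(self.values[self.ids.index(i), self.ids.index(j)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class CallRateReport:
    """Individuals/loci removed by the call-rate filter, per pass."""

    removed_individuals: list[str]
    removed_loci: list[str]
    n_passes: int


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def filter_call_rate(
    g: GenotypeMatrix, threshold: float = 0.70
) -> tuple[GenotypeMatrix, CallRateReport]:
    """Remove individuals and loci with call rate below ``threshold``.

    Removal is iterated to a fixed point (individuals first, then loci in
    each pass) so the result does not depend on which side is considered
    first: dropping a poorly-called individual can lift a locus above the
    threshold and vice versa.

    Returns the filtered copy and a :class:`CallRateReport`.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    keep_ids = list(g.ids)
    keep_loci = list(g.loci)
    dos = g.dosages.copy()
    removed_i: list[str] = []
    removed_l: list[str] = []
    n_passes = 0
    while True:
        n_passes += 1
        changed = False
        with np.errstate(invalid="ignore"):
            cr_i = 1.0 - np.isnan(dos).mean(axis=1)
        drop_i = cr_i < threshold
        if drop_i.any():
            removed_i.extend(np.array(keep_ids)[drop_i])
            keep_ids = list(np.array(keep_ids)[~drop_i])
            dos = dos[~drop_i]
            changed = True
        if len(keep_ids) == 0:
            raise ValueError(
                f"call-rate filter at threshold {threshold} removed all individuals"
            )
        cr_l = 1.0 - np.isnan(dos).mean(axis=0)
        drop_l = cr_l < threshold
        if drop_l.any():
            removed_l.extend(np.array(keep_loci)[drop_l])
            keep_loci = list(np.array(keep_loci)[~drop_l])
            dos = dos[:, ~drop_l]
            changed = True
        if not changed:
            break
    filtered = GenotypeMatrix(
        ids=keep_ids,
        loci=keep_loci,
        dosages=dos,
        metadata=g.metadata.loc[keep_ids].copy(),
    )
    return filtered, CallRateReport(removed_i, removed_l, n_passes)


# ---------------------------------------------------------------------------
# Allele frequencies and the GRM
# ---------------------------------------------------------------------------

def allele_frequencies(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus alternate-allele frequency from non-missing dosages.

    Returns a frame indexed by locus with columns ``freq``, ``n_called``
    and ``monomorphic`` (True where p is exactly 0 or 1).
    """
    n_called = (~np.isnan(g.dosages)).sum(axis=0)
    if (n_called == 0).any():
        bad = np.array(g.loci)[n_called == 0]
        raise ValueError(f"loci with zero non-missing calls: {list(bad[:5])}")
    p = np.nansum(g.dosages, axis=0) / (2.0 * n_called)
    return pd.DataFrame(
        {
            "freq": p,
            "n_called": n_called,
            "monomorphic": (p == 0.0) | (p == 1.0),
        },
        index=pd.Index(g.loci, name="locus"),
    )


def grm_gcta(
    g: GenotypeMatrix,
    freqs: pd.DataFrame | None = None,
    min_freq: float | None = None,
) -> RelatednessMatrix:
    """GCTA genomic relatedness matrix with pairwise-complete loci.

    Monomorphic and near-monomorphic loci (p < 1/(2n) by default, or
    ``min_freq`` if given) are dropped before estimation to avoid division
    by ~0 in the 2p(1-p) standardisation.

    Pairs sharing zero called loci get a NaN entry (reported via the
    ``n_loci_pair`` matrix, which is 0 there).
    """
    if freqs is None:
        freqs = allele_frequencies(g)
    p = freqs["freq"].to_numpy(dtype=float)
    n = g.n_individuals
    if min_freq is None:
        min_freq = 1.0 / (2.0 * n)
    keep = (p >= min_freq) & (p <= 1.0 - min_freq)
    if keep.sum() == 0:
        raise ValueError("no polymorphic loci left for the GRM")
    x = g.dosages[:, keep]
    p = p[keep]

    denom = 2.0 * p * (1.0 - p)
    obs = ~np.isnan(x)
    xz = np.where(obs, x, 0.0)

    # Off-diagonal: sum_i (x_j - 2p)(x_k - 2p)/(2p(1-p)) over shared loci.
    # Expand so each factor is zero at missing entries and cross terms add up:
    # with a = x/sqrt(d), b = 2p/sqrt(d):
    # sum (a_j - b)(a_k - b) = A A^T - A Bobs^T - Bobs A^T + C
    sd = np.sqrt(denom)
    a = np.where(obs, xz / sd, 0.0)
    b = 2.0 * p / sd
    bobs = np.where(obs, b, 0.0)
    num = (
        a @ a.T
        - a @ bobs.T
        - bobs @ a.T
        + bobs @ bobs.T
    )
    m_pair = obs.astype(np.int64) @ obs.astype(np.int64).T
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(m_pair > 0, num / np.maximum(m_pair, 1), np.nan)

    # Diagonal uses the inbreeding-style estimator, own loci only.
    diag_terms = np.where(
        obs, (xz * xz - (1.0 + 2.0 * p) * xz + 2.0 * p * p) / denom, 0.0
    )
    m_self = obs.sum(axis=1)
    diag = 1.0 + diag_terms.sum(axis=1) / m_self
    values[np.diag_indices(n)] = diag
    m_pair[np.diag_indices(n)] = m_self
    return RelatednessMatrix(ids=list(g.ids), values=values, n_loci_pair=m_pair)


# ---------------------------------------------------------------------------
# I/O: tabular dosage CSV, minimal VCF 4.2, long-format GRM
# ---------------------------------------------------------------------------

def write_dosage_csv(g: GenotypeMatrix, path) -> None:
    """Rows = individuals, columns = loci, values 0/1/2, "NA" for missing."""
    df = pd.DataFrame(g.dosages, index=g.ids, columns=g.loci)
    out = df.where(df.notna(), other=np.nan)
    out.index.name = "id"
    # dosages are integral by construction; format as ints with NA
    out = out.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.to_csv(path)


def read_dosage_csv(path, metadata: pd.DataFrame | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0, na_values=["NA"], dtype=str)
    dosages = df.apply(pd.to_numeric).to_numpy(dtype=float)
    return GenotypeMatrix(
        ids=list(df.index.astype(str)),
        loci=list(df.columns.astype(str)),
        dosages=dosages,
        metadata=metadata,
    )


_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(g: GenotypeMatrix, path, chrom: str = "1") -> None:
    """Minimal VCF 4.2 with GT only; one record per locus, REF=A ALT=G."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.ids)
            + "\n"
        )
        for j, locus in enumerate(g.loci):
            gts = [
                "./." if np.isnan(v) else _GT_CODE[v] for v in g.dosages[:, j]
            ]
            fh.write(
                f"{chrom}\t{j + 1}\t{locus}\tA\tG\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path, metadata: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a GT-only biallelic VCF into a dosage matrix.

    Multiallelic records are rejected with a clear error.  Uses cyvcf2 when
    available and falls back to a plain-text reader otherwise (the minimal
    files written by :func:`write_vcf` are valid input to both).
    """
    try:
        from cyvcf2 import VCF  # type: ignore
    except ImportError:
        VCF = None
    path = str(path)
    if VCF is not None:
        vcf = VCF(path)
        ids = list(vcf.samples)
        loci: list[str] = []
        rows: list[np.ndarray] = []
        for rec in vcf:
            if len(rec.ALT) != 1:
                raise ValueError(
                    f"multiallelic record at {rec.CHROM}:{rec.POS} not supported"
                )
            loci.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
            gt = np.asarray(rec.genotype.array())[:, :2].astype(float)
            gt[gt < 0] = np.nan
            rows.append(gt.sum(axis=1))
        dosages = np.column_stack(rows) if rows else np.empty((len(ids), 0))
        return GenotypeMatrix(ids=ids, loci=loci, dosages=dosages, metadata=metadata)
    return _read_vcf_text(path, metadata)


def _read_vcf_text(path, metadata: pd.DataFrame | None) -> GenotypeMatrix:
    ids: list[str] = []
    loci: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                ids = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            chrom, pos, vid, _ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            if "," in alt:
                raise ValueError(f"multiallelic record at {chrom}:{pos} not supported")
            loci.append(vid if vid != "." else f"{chrom}:{pos}")
            fmt = parts[8].split(":")
            gt_idx = fmt.index("GT")
            row = []
            for cell in parts[9:]:
                gt = cell.split(":")[gt_idx].replace("|", "/")
                if "." in gt:
                    row.append(np.nan)
                else:
                    row.append(float(sum(int(a) for a in gt.split("/"))))
            rows.append(row)
    dosages = np.array(rows, dtype=float).T if rows else np.empty((len(ids), 0))
    return GenotypeMatrix(ids=ids, loci=loci, dosages=dosages, metadata=metadata)


def write_grm_csv(grm: RelatednessMatrix, path) -> None:
    """Long format: id1,id2,relatedness,n_loci (upper triangle incl. diagonal)."""
    records = []
    n = len(grm.ids)
    for i in range(n):
        for j in range(i, n):
            records.append(
                (
                    grm.ids[i],
                    grm.ids[j],
                    grm.values[i, j],
                    int(grm.n_loci_pair[i, j]),
                )
            )
    pd.DataFrame(
        records, columns=["id1", "id2", "relatedness", "n_loci"]
    ).to_csv(path, index=False)
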