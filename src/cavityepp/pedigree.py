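"""Social pedigree from field records and expected additive relatedness.

The field-observed (social) pedigree records which adults attended which
nest.  Expected additive relatedness between individuals follows the tabular
(recursive) numerator-relationship method:

    a_ii = 1 + a_{sire(i), dam(i)} / 2
    a_ij = (a_{i, sire(j)} + a_{i, dam(j)}) / 2     for j not an ancestor of i

with unknown parents contributing 0.  This is the baseline the genomic
relatedness matrix is compared against: a mismatch between the social value
(e.g. 0.5 for father-offspring) and the realized genomic value is the signal
for extra-pair paternity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SocialPedigree",
    "RelatednessBand",
    "RELATEDNESS_BANDS",
    "build_pedigree",
    "expected_relatedness",
    "social_relatedness_matrix",
    "read_pedigree_csv",
    "write_pedigree_csv",
]


@dataclass(frozen=True)
class RelatednessBand:
    """Named relatedness class used to bin GRM values for display."""

    label: str
    center: float
    display_interval: tuple[float, float]


#: The display bands: sixteenth (purple), eighth (orange), quarter (blue,
#: half-siblings) and half (yellow, full siblings / parent-offspring).
RELATEDNESS_BANDS: tuple[RelatednessBand, ...] = (
    RelatednessBand("sixteenth", 1 / 16, (0.0, 0.1)),
    RelatednessBand("eighth", 1 / 8, (0.1, 0.15)),
    RelatednessBand("quarter", 1 / 4, (0.15, 0.35)),
    RelatednessBand("half", 1 / 2, (0.35, 1.0)),
)
assert all(
    a.center < b.center for a, b in zip(RELATEDNESS_BANDS, RELATEDNESS_BANDS[1:])
)


@dataclass
class SocialPedigree:
    """id -> (mother, father, cohort year, natal nest); None for unknown."""

    entries: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = ["mother", "father", "year", "natal_nest"]
        if self.entries.empty:
            self.entries = pd.DataFrame(
                columns=required, index=pd.Index([], name="id")
            )
        missing = [c for c in required if c not in self.entries.columns]
        if missing:
            raise ValueError(f"pedigree table missing columns {missing}")
        if self.entries.index.has_duplicates:
            dupes = self.entries.index[self.entries.index.duplicated()]
            raise ValueError(f"duplicate pedigree ids: {list(dupes[:5])}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(i: str, stack: list[str]) -> None:
            if i not in self.entries.index:
                return
            s = state.get(i)
            if s == 1:
                return
            if s == 0:
                raise ValueError(
                    f"pedigree cycle: {' -> '.join(stack + [i])}"
                )
            state[i] = 0
            for p in (self.mother_of(i), self.father_of(i)):
                if p is not None:
                    visit(p, stack + [i])
            state[i] = 1

        for i in self.entries.index:
            visit(str(i), [])

    @property
    def ids(self) -> list[str]:
        return [str(i) for i in self.entries.index]

    def __contains__(self, i: str) -> bool:
        return i in self.entries.index

    def _parent(self, i: str, which: str) -> str | None:
        if i not in self.entries.index:
            return None
        v = self.entries.at[i, which]
        return None if pd.isna(v) or v == "" else str(v)

    def mother_of(self, i: str) -> str | None:
        return self._parent(i, "mother")

    def father_of(self, i: str) -> str | None:
        return self._parent(i, "father")

    def founders(self) -> list[str]:
        return [
            i for i in self.ids
            if self.mother_of(i) is None and self.father_of(i) is None
        ]


def build_pedigree(nest_records: pd.DataFrame) -> SocialPedigree:
    """Assemble the social pedigree from nest records.

    ``nest_records`` must have one row per nest with columns ``nest_id``,
    ``year``, ``mother_id``, ``father_id`` and ``offspring_ids`` (an
    iterable of nestling ids, or a ';'-joined string).  Parents appear as
    founder entries unless they are themselves linked as offspring of an
    earlier nest (recruits across years keep their natal links).
    """
    rows: dict[str, dict] = {}

    def ensure(i: str | None, **kw) -> None:
        if i is None or (isinstance(i, float) and np.isnan(i)) or i == "":
            return
        i = str(i)
        entry = rows.setdefault(
            i, {"mother": None, "father": None, "year": None, "natal_nest": None}
        )
        for k, v in kw.items():
            if v is not None:
                if entry[k] is not None and entry[k] != v:
                    raise ValueError(
                        f"conflicting {k} for {i}: {entry[k]} vs {v}"
                    )
                entry[k] = v

    for _, rec in nest_records.iterrows():
        mother = rec.get("mother_id")
        father = rec.get("father_id")
        ensure(mother)
        ensure(father)
        offspring = rec.get("offspring_ids", [])
        if isinstance(offspring, str):
            offspring = [o for o in offspring.split(";") if o]
        for off in offspring:
            ensure(
                str(off),
                mother=None if pd.isna(mother) or mother == "" else str(mother),
                father=None if pd.isna(father) or father == "" else str(father),
                year=rec.get("year"),
                natal_nest=str(rec.get("nest_id")),
            )
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "id"
    return SocialPedigree(entries=df)


def expected_relatedness(ped: SocialPedigree, i: str, j: str) -> float:
    """Additive relationship a_ij by the tabular (recursive) method."""
    for x in (i, j):
        if x not in ped:
            raise KeyError(f"id {x!r} not in pedigree")
    return _tabular(ped, str(i), str(j), {})


def _depth(ped: SocialPedigree, i: str, cache: dict) -> int:
    if i in cache:
        return cache[i]
    parents = [p for p in (ped.mother_of(i), ped.father_of(i)) if p is not None]
    d = 0 if not parents else 1 + max(_depth(ped, p, cache) for p in parents)
    cache[i] = d
    return d


def _tabular(ped: SocialPedigree, i: str, j: str, memo: dict) -> float:
    key = (i, j) if i <= j else (j, i)
    if key in memo:
        return memo[key]
    if i == j:
        m, f = ped.mother_of(i), ped.father_of(i)
        inbr = _tabular(ped, m, f, memo) if (m and f) else 0.0
        val = 1.0 + 0.5 * inbr
    else:
        # recurse through the parents of the individual with the *younger*
        # (deeper) pedigree position, so ancestors are never expanded through
        # their descendants
        dcache: dict = {}
        if _depth(ped, j, dcache) < _depth(ped, i, dcache):
            i, j = j, i
        m, f = ped.mother_of(j), ped.father_of(j)
        am = _tabular(ped, i, m, memo) if m else 0.0
        af = _tabular(ped, i, f, memo) if f else 0.0
        val = 0.5 * (am + af)
    memo[key] = val
    return val


def social_relatedness_matrix(ped: SocialPedigree, ids: list[str]) -> np.ndarray:
    """Symmetric matrix of expected relatedness in the given id order."""
    for x in ids:
        if x not in ped:
            raise KeyError(f"id {x!r} not in pedigree")
    n = len(ids)
    out = np.zeros((n, n))
    memo: dict = {}
    for a in range(n):
        for b in range(a, n):
            v = _tabular(ped, str(ids[a]), str(ids[b]), memo)
            out[a, b] = out[b, a] = v
    return out


def write_pedigree_csv(ped: SocialPedigree, path) -> None:
    df = ped.entries.copy()
    df = df.fillna("")
    df.to_csv(path)


def read_pedigree_csv(path) -> SocialPedigree:
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    df = df.replace({"": None})
    df.index = df.index.astype(str)
    if "year" in df.columns:
        df["year"] = pd.to_numeric(df["year"], errors="coerce")
    return SocialPedigree(entries=df)
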