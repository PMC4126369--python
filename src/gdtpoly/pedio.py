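"""Merlin/QTDT pedigree file handling, kinship, and analysis-sample assembly.

This module reads and writes the whitespace-delimited Merlin/QTDT trio of
files (``.ped``, ``.dat``, ``.map``) plus Merlin-style per-pair IBD tables,
computes kinship coefficients recursively on each pedigree, and assembles the
per-family analysis samples consumed by the score machinery: for each family,
the genotyped members with an observed phenotype, their outcome category
``Y in {1..K}``, and their genotypes coded as the proportion of a counted
allele (0, 1/2 or 1).

Affection traits are coded 1 = unaffected, 2 = affected, 0 or ``x`` =
missing.  Marker genotypes are two allele tokens per marker, ``0`` = missing.
All readers transparently accept gzip-compressed files.
"""

from __future__ import annotations

import gzip
import io
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

MISSING_ALLELE = "0"


class PedigreeError(ValueError):
    """Raised on malformed pedigree structure or files."""


# ---------------------------------------------------------------------------
# pedigree structure and kinship
# ---------------------------------------------------------------------------

@dataclass
class Pedigree:
    """One family's structure: member ids, parent links and sex codes.

    ``father``/``mother`` hold integer indices into ``ids`` (-1 for
    founders).  A member is a founder iff both parent indices are -1; having
    exactly one known parent is rejected.
    """

    fam: str
    ids: list[str]
    father: np.ndarray
    mother: np.ndarray
    sex: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.father = np.asarray(self.father, dtype=int)
        self.mother = np.asarray(self.mother, dtype=int)
        self.sex = np.asarray(self.sex, dtype=int)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            dup = [k for k, c in Counter(self.ids).items() if c > 1]
            raise PedigreeError(f"family {self.fam}: duplicated member id(s) {dup}")
        for arr in (self.father, self.mother):
            if arr.shape != (n,) or (arr >= n).any() or (arr < -1).any():
                raise PedigreeError(f"family {self.fam}: bad parent index array")
        if ((self.father < 0) != (self.mother < 0)).any():
            bad = self.ids[int(np.argmax((self.father < 0) != (self.mother < 0)))]
            raise PedigreeError(
                f"family {self.fam}: member {bad} has exactly one known parent"
            )
        g = nx.DiGraph()
        g.add_nodes_from(range(n))
        for i in range(n):
            if self.father[i] >= 0:
                g.add_edge(self.father[i], i)
                g.add_edge(self.mother[i], i)
        if not nx.is_directed_acyclic_graph(g):
            raise PedigreeError(f"family {self.fam}: pedigree graph is cyclic")
        self._topo = list(nx.topological_sort(g))

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def founder(self) -> np.ndarray:
        return self.father < 0

    @property
    def topological_order(self) -> list[int]:
        """Member indices, every parent before any of its children."""
        return list(self._topo)

    def index(self, member_id: str) -> int:
        return self.ids.index(str(member_id))

    def kinship(self) -> np.ndarray:
        """Kinship matrix phi via the standard recursive definition.

        Founders are mutually unrelated with phi_ii = 1/2; for a non-founder
        i processed after j, phi_ij = (phi_{father(i),j} + phi_{mother(i),j})/2
        and phi_ii = (1 + phi_{father(i),mother(i)})/2.
        """
        n = self.n
        phi = np.zeros((n, n))
        for i in self._topo:
            fa, mo = self.father[i], self.mother[i]
            if fa < 0:
                phi[i, i] = 0.5
            else:
                phi[i, i] = 0.5 * (1.0 + phi[fa, mo])
            for j in self._topo:
                if j == i:
                    break
                v = 0.0 if fa < 0 else 0.5 * (phi[fa, j] + phi[mo, j])
                phi[i, j] = phi[j, i] = v
        return phi


# ---------------------------------------------------------------------------
# Merlin/QTDT files
# ---------------------------------------------------------------------------

@dataclass
class FamilyData:
    """Raw per-family content of a .ped file: structure, traits, genotypes."""

    pedigree: Pedigree
    traits: dict[str, np.ndarray]            # trait name -> 0/1/nan per member
    genotypes: dict[str, np.ndarray]         # marker name -> (n, 2) allele tokens


@dataclass
class PedData:
    families: dict[str, FamilyData]
    trait_names: list[str]
    marker_names: list[str]
    positions: dict[str, tuple[str, float]] = field(default_factory=dict)

    def pedigrees(self) -> dict[str, Pedigree]:
        return {f: d.pedigree for f, d in self.families.items()}


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def read_datfile(path) -> list[tuple[str, str]]:
    """Parse a Merlin .dat file into (code, name) pairs; codes A, M, T, C, S."""
    items = []
    with _open_text(path) as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            code = tok[0].upper()
            if code not in {"A", "M", "T", "C", "S", "S2"}:
                raise PedigreeError(f"{path}: unknown .dat field code {tok[0]!r}")
            items.append((code, tok[1] if len(tok) > 1 else ""))
    return items


def _parse_affection(token: str, where: str) -> float:
    t = token.lower()
    if t in {"0", "x", "na", "-"}:
        return np.nan
    if t == "1":
        return 0.0
    if t == "2":
        return 1.0
    raise PedigreeError(f"{where}: bad affection code {token!r}")


def read_pedigree(ped_path, dat_path) -> PedData:
    """Read a Merlin/QTDT .ped/.dat pair into validated structures.

    Affection traits are mapped to 0/1 with NaN for missing; quantitative
    traits and covariates are read as floats ('x' missing); skipped columns
    are discarded.  Marker alleles are kept as string tokens.
    """
    items = read_datfile(dat_path)
    trait_names = [name for code, name in items if code in {"A", "T", "C"}]
    marker_names = [name for code, name in items if code == "M"]

    rows: dict[str, list] = {}
    with _open_text(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            ncol = 5 + sum(2 if c == "M" else 1 for c, _ in items)
            if len(tok) != ncol:
                raise PedigreeError(
                    f"{ped_path}:{lineno}: expected {ncol} columns, got {len(tok)}"
                )
            rows.setdefault(tok[0], []).append((lineno, tok))

    families: dict[str, FamilyData] = {}
    for fam, famrows in rows.items():
        ids = [t[1] for _, t in famrows]
        if len(set(ids)) != len(ids):
            dup = [k for k, c in Counter(ids).items() if c > 1]
            raise PedigreeError(f"family {fam}: duplicated member id(s) {dup}")
        idx = {mid: i for i, mid in enumerate(ids)}
        father = np.full(len(ids), -1)
        mother = np.full(len(ids), -1)
        sex = np.zeros(len(ids), dtype=int)
        traits = {name: np.full(len(ids), np.nan) for name in trait_names}
        genos = {
            name: np.full((len(ids), 2), MISSING_ALLELE, dtype=object)
            for name in marker_names
        }
        for i, (lineno, tok) in enumerate(famrows):
            for parent, arr in ((tok[2], father), (tok[3], mother)):
                if parent not in {"0", "x"}:
                    if parent not in idx:
                        raise PedigreeError(
                            f"{ped_path}:{lineno}: family {fam} member {tok[1]}: "
                            f"unknown parent id {parent!r}"
                        )
                    arr[i] = idx[parent]
            sex[i] = int(tok[4]) if tok[4].isdigit() else 0
            col = 5
            for code, name in items:
                if code == "M":
                    genos[name][i] = (tok[col], tok[col + 1])
                    col += 2
                else:
                    if code == "A":
                        traits[name][i] = _parse_affection(
                            tok[col], f"{ped_path}:{lineno}"
                        )
                    elif code in {"T", "C"}:
                        t = tok[col].lower()
                        traits[name][i] = np.nan if t in {"x", "na", "-"} else float(tok[col])
                    col += 1
        ped = Pedigree(fam, ids, father, mother, sex)
        families[fam] = FamilyData(ped, traits, genos)
    return PedData(families, trait_names, marker_names)


def write_pedigree(
    peddata: PedData,
    ped_path,
    dat_path,
    map_path=None,
    trait_codes: dict[str, str] | None = None,
) -> None:
    """Write PedData back to Merlin/QTDT files (inverse of read_pedigree)."""
    codes = trait_codes or {name: "A" for name in peddata.trait_names}
    with open(dat_path, "w") as fh:
        for name in peddata.trait_names:
            fh.write(f"{codes.get(name, 'A')} {name}\n")
        for name in peddata.marker_names:
            fh.write(f"M {name}\n")
    with open(ped_path, "w") as fh:
        for fam, fd in peddata.families.items():
            ped = fd.pedigree
            for i, mid in enumerate(ped.ids):
                fa = ped.ids[ped.father[i]] if ped.father[i] >= 0 else "0"
                mo = ped.ids[ped.mother[i]] if ped.mother[i] >= 0 else "0"
                row = [fam, mid, fa, mo, str(ped.sex[i])]
                for name in peddata.trait_names:
                    v = fd.traits[name][i]
                    if codes.get(name, "A") == "A":
                        row.append("x" if np.isnan(v) else str(int(v) + 1))
                    else:
                        row.append("x" if np.isnan(v) else repr(float(v)))
                for name in peddata.marker_names:
                    row.extend(str(a) for a in fd.genotypes[name][i])
                fh.write(" ".join(row) + "\n")
    if map_path is not None:
        with open(map_path, "w") as fh:
            fh.write("CHROMOSOME MARKER POSITION\n")
            for name in peddata.marker_names:
                chrom, pos = peddata.positions.get(name, ("1", 0.0))
                fh.write(f"{chrom} {name} {pos}\n")


def read_map(path):
    """Read a Merlin .map file into {marker: (chromosome, position)}."""
    out = {}
    with _open_text(path) as fh:
        for line in fh:
            tok = line.split()
            if not tok or tok[0].upper() in {"CHROMOSOME", "CHR"}:
                continue
            out[tok[1]] = (tok[0], float(tok[2]))
    return out


# ---------------------------------------------------------------------------
# IBD tables
# ---------------------------------------------------------------------------

def read_ibd(path, marker: str, pedigrees: dict[str, Pedigree]) -> dict[str, np.ndarray]:
    """Read Merlin-style IBD sharing probabilities for one marker.

    The file is a whitespace table with columns FAMILY, ID1, ID2, MARKER,
    P(IBD=0), P(IBD=1), P(IBD=2); the sharing proportion for a pair is
    pi = P(IBD=1)/2 + P(IBD=2).  Pairs absent from the file fall back to
    twice the kinship coefficient (with a logged warning); a header line is
    tolerated.
    """
    pis = {}
    seen = {}
    for fam, ped in pedigrees.items():
        pis[fam] = 2.0 * ped.kinship()
        seen[fam] = np.eye(ped.n, dtype=bool)
    nrows = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok or tok[0].upper() in {"FAMILY", "FAM"}:
                continue
            if len(tok) < 7:
                raise PedigreeError(f"{path}:{lineno}: expected 7 columns")
            fam, id1, id2, mk = tok[0], tok[1], tok[2], tok[3]
            if mk != marker or fam not in pis:
                continue
            p = np.array([float(x) for x in tok[4:7]])
            if abs(p.sum() - 1.0) > 1e-6:
                raise PedigreeError(
                    f"{path}:{lineno}: IBD probabilities sum to {p.sum():.8f}, not 1"
                )
            ped = pedigrees[fam]
            i, j = ped.index(id1), ped.index(id2)
            pi = 0.5 * p[1] + p[2]
            pis[fam][i, j] = pis[fam][j, i] = pi
            seen[fam][i, j] = seen[fam][j, i] = True
            nrows += 1
    for fam, mask in seen.items():
        nmiss = int((~mask).sum() // 2)
        if nmiss and nrows:
            logger.warning(
                "IBD file %s, marker %s: %d pair(s) of family %s absent; "
                "defaulting to twice the kinship coefficient",
                path, marker, nmiss, fam,
            )
    return pis


# ---------------------------------------------------------------------------
# analysis samples
# ---------------------------------------------------------------------------

# Fixed mapping from two dichotomous traits (Y1 = endophenotype, Y2 = disease)
# to the four outcome categories; category K = 4 (neither) is the reference.
CATEGORY_OF = {(1, 0): 1, (0, 1): 2, (1, 1): 3, (0, 0): 4}


@dataclass
class FamilySample:
    """One family's analysis sample, ordered by outcome category.

    Holds the genotyped members with an observed phenotype, their category
    ``y`` in 1..K (members sorted so category 1 comes first and the reference
    category K last), genotype proportions ``x1``/``x2`` in {0, 1/2, 1}, and
    relatedness matrices aligned to the retained members: ``kin2`` is twice
    the kinship matrix, ``pi1``/``pi2`` the per-locus IBD sharing proportions
    (defaulting to ``kin2`` when unknown).
    """

    fam: str
    ids: list[str]
    y: np.ndarray
    K: int
    kin2: np.ndarray
    x1: np.ndarray | None = None
    x2: np.ndarray | None = None
    pi1: np.ndarray | None = None
    pi2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if self.K < 2:
            raise ValueError("K must be at least 2")
        if self.y.size and ((self.y < 1) | (self.y > self.K)).any():
            raise ValueError(f"family {self.fam}: category outside 1..{self.K}")
        if (np.diff(self.y) < 0).any():
            raise ValueError(f"family {self.fam}: members not ordered by category")

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def n_k(self) -> np.ndarray:
        return np.bincount(self.y, minlength=self.K + 1)[1:]

    @property
    def informative(self) -> bool:
        """False when every retained member is in a single category."""
        return len(np.unique(self.y)) > 1

    def relatedness(self, locus: int, null_mode: str = "assoc") -> np.ndarray:
        """Relatedness matrix for one locus: IBD pi under the association-only
        null ("assoc"), twice the kinship under "linkage-assoc" or when IBD
        is unavailable."""
        if null_mode == "linkage-assoc":
            return self.kin2
        if null_mode != "assoc":
            raise ValueError(f"unknown null mode {null_mode!r}")
        pi = self.pi1 if locus == 1 else self.pi2
        if pi is None:
            logger.warning(
                "family %s: no IBD at locus %d under the association-only null; "
                "falling back to twice the kinship coefficients", self.fam, locus,
            )
            return self.kin2
        return pi


def allele_proportions(
    genotypes: np.ndarray, counted_allele: str
) -> np.ndarray:
    """Proportion of the counted allele per genotype row; NaN when missing."""
    g = np.asarray(genotypes, dtype=object)
    miss = (g == MISSING_ALLELE).any(axis=1)
    prop = (g == counted_allele).sum(axis=1) / 2.0
    prop = prop.astype(float)
    prop[miss] = np.nan
    return prop


def default_counted_allele(peddata: PedData, marker: str) -> str:
    """Minor allele among founders, pooled across families (ties: smaller token)."""
    counts: Counter = Counter()
    for fd in peddata.families.values():
        fmask = fd.pedigree.founder
        for a in fd.genotypes[marker][fmask].ravel():
            if a != MISSING_ALLELE:
                counts[str(a)] += 1
    if not counts:
        raise PedigreeError(f"marker {marker}: no genotyped founder allele")
    return min(counts, key=lambda a: (counts[a], a))


def build_family_samples(
    peddata: PedData,
    traits: tuple[str, ...],
    marker_x2: str | None,
    marker_x1: str | None = None,
    counted_alleles: dict[str, str] | None = None,
    ibd: dict[str, dict[str, np.ndarray]] | None = None,
) -> list[FamilySample]:
    """Assemble FamilySample objects for a (conditioning, tested) marker pair.

    ``traits`` is a single affection trait name (K = 2) or a pair
    (endophenotype, disease) combined into K = 4 categories via the fixed
    mapping ``CATEGORY_OF``.  Members with a missing phenotype or a missing
    genotype at any required marker are excluded.  ``ibd`` maps marker name
    -> family -> pi matrix on the full pedigree (as from :func:`read_ibd`).
    """
    if len(traits) not in (1, 2):
        raise ValueError("traits must name one or two affection traits")
    K = 2 if len(traits) == 1 else 4
    counted = dict(counted_alleles or {})
    for mk in filter(None, (marker_x1, marker_x2)):
        counted.setdefault(mk, default_counted_allele(peddata, mk))

    samples = []
    for fam, fd in peddata.families.items():
        ped = fd.pedigree
        cols = {}
        keep = np.ones(ped.n, dtype=bool)
        for slot, mk in (("x1", marker_x1), ("x2", marker_x2)):
            if mk is None:
                continue
            cols[slot] = allele_proportions(fd.genotypes[mk], counted[mk])
            keep &= ~np.isnan(cols[slot])
        tvals = [fd.traits[t] for t in traits]
        for tv in tvals:
            keep &= ~np.isnan(tv)
        if K == 2:
            y = np.where(tvals[0] == 1, 1, 2)
        else:
            y = np.array(
                [
                    CATEGORY_OF.get((int(a), int(b)), 0) if keep[i] else 0
                    for i, (a, b) in enumerate(
                        zip(np.nan_to_num(tvals[0]), np.nan_to_num(tvals[1]))
                    )
                ]
            )
        idx = np.flatnonzero(keep)
        idx = idx[np.argsort(y[idx], kind="stable")]
        kin2 = 2.0 * ped.kinship()
        sub = np.ix_(idx, idx)
        pis = {}
        for slot, mk in (("pi1", marker_x1), ("pi2", marker_x2)):
            if mk is not None and ibd and mk in ibd and fam in ibd[mk]:
                pis[slot] = ibd[mk][fam][sub]
            else:
                pis[slot] = None
        samples.append(
            FamilySample(
                fam=fam,
                ids=[ped.ids[i] for i in idx],
                y=y[idx],
                K=K,
                kin2=kin2[sub],
                x1=cols["x1"][idx] if "x1" in cols else None,
                x2=cols["x2"][idx] if "x2" in cols else None,
                pi1=pis["pi1"],
                pi2=pis["pi2"],
            )
        )
    return samples
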