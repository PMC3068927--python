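"""Domain types and tabular I/O for chemical-protein interactome analyses.

The central object is a pockets x drugs score matrix (rows are protein
binding pockets, columns are drug molecules) with an explicit missing-value
mask: array docking fails for some chemical/pocket combinations, and those
gaps must survive every downstream transformation.  Everything is plain
TSV/GMT so matrices, rosters, pocket annotations, gene sets and probe maps
round-trip through files without loss.
"""

from __future__ import annotations

import dataclasses
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ScoreMatrix",
    "ZMatrix",
    "BinaryMatrix",
    "DrugRoster",
    "PocketRecord",
    "PocketAnnotation",
    "GeneSet",
    "ProbeGeneMap",
    "Roles",
    "read_score_matrix",
    "write_score_matrix",
    "read_roster",
    "write_roster",
    "read_annotations",
    "read_gmt",
    "read_probe_map",
]

#: Allowed drug roles in a case/control roster.
Roles = ("case", "control", "background")

DEFAULT_MISSING_TOKEN = "NA"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class ScoreMatrix:
    """A pockets x drugs real matrix with an explicit missing mask.

    ``values[i, j]`` is the score of drug ``drug_ids[j]`` docked into pocket
    ``pocket_ids[i]``; ``missing[i, j]`` is True where no score exists.
    Masked cells of ``values`` hold NaN but the mask, not NaN, is
    authoritative.
    """

    drug_ids: list[str]
    pocket_ids: list[str]
    values: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        self.drug_ids = list(self.drug_ids)
        self.pocket_ids = list(self.pocket_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        _check_unique(self.drug_ids, "drug")
        _check_unique(self.pocket_ids, "pocket")
        shape = (len(self.pocket_ids), len(self.drug_ids))
        if self.values.shape != shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"(n_pockets, n_drugs) = {shape}"
            )
        if self.missing.shape != self.values.shape:
            raise ValueError("missing mask shape does not match values")
        self.values = self.values.copy()
        self.values[self.missing] = np.nan

    @property
    def n_pockets(self) -> int:
        return len(self.pocket_ids)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    def drug_index(self, drug_id: str) -> int:
        try:
            return self.drug_ids.index(drug_id)
        except ValueError:
            raise KeyError(f"unknown drug id: {drug_id!r}") from None

    def pocket_index(self, pocket_id: str) -> int:
        try:
            return self.pocket_ids.index(pocket_id)
        except ValueError:
            raise KeyError(f"unknown pocket id: {pocket_id!r}") from None

    def drug_column(self, drug_id: str) -> np.ndarray:
        """Column of one drug across pockets, masked cells as NaN."""
        return self.values[:, self.drug_index(drug_id)]

    def pocket_row(self, pocket_id: str) -> np.ndarray:
        """Row of one pocket across drugs, masked cells as NaN."""
        return self.values[self.pocket_index(pocket_id)]

    def validate(self) -> list[str]:
        """Return human-readable warnings (fully missing rows/columns)."""
        notes = []
        for i, pid in enumerate(self.pocket_ids):
            if self.missing[i].all():
                notes.append(f"pocket {pid!r} is fully missing")
        for j, did in enumerate(self.drug_ids):
            if self.missing[:, j].all():
                notes.append(f"drug {did!r} is fully missing")
        return notes

    def __eq__(self, other: object) -> bool:  # value equality incl. mask
        if not isinstance(other, ScoreMatrix):
            return NotImplemented
        return (
            self.drug_ids == other.drug_ids
            and self.pocket_ids == other.pocket_ids
            and np.array_equal(self.missing, other.missing)
            and np.array_equal(
                self.values[~self.missing], other.values[~other.missing]
            )
        )


class ZMatrix(ScoreMatrix):
    """A ScoreMatrix whose values are Z'-scores (column- then row-normalized).

    Smaller (more negative) Z' means stronger theoretical binding.
    """


class BinaryMatrix(ScoreMatrix):
    """Interactive/not-interactive calls (1.0/0.0) with the same missing mask."""

    def interactive(self) -> np.ndarray:
        """Boolean array; missing cells are False (use .missing to exclude)."""
        return (self.values == 1.0) & ~self.missing


@dataclass
class DrugRoster:
    """Per-drug role (case / control / background) and optional variant group.

    A variant group ties together ionization states or metabolites of one
    parent drug; analyses that pick a representative variant pair consult it.
    """

    roles: dict[str, str]
    variant_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for drug, role in self.roles.items():
            if role not in Roles:
                raise ValueError(
                    f"unknown role {role!r} for drug {drug!r}; "
                    f"allowed roles: {', '.join(Roles)}"
                )
        unknown = set(self.variant_groups) - set(self.roles)
        if unknown:
            raise ValueError(f"variant group for unrostered drugs: {sorted(unknown)}")

    def drugs_with_role(self, role: str) -> list[str]:
        if role not in Roles:
            raise ValueError(f"unknown role {role!r}; allowed: {', '.join(Roles)}")
        return [d for d, r in self.roles.items() if r == role]

    @property
    def cases(self) -> list[str]:
        return self.drugs_with_role("case")

    @property
    def controls(self) -> list[str]:
        return self.drugs_with_role("control")

    def variants_of(self, group: str) -> list[str]:
        return [d for d, g in self.variant_groups.items() if g == group]

    def check_covers(self, drug_ids: Iterable[str]) -> None:
        missing = [d for d in drug_ids if d not in self.roles]
        if missing:
            raise ValueError(f"drugs without a rostered role: {missing[:5]}")


@dataclass
class PocketRecord:
    """Annotation of one protein pocket."""

    pocket_id: str
    pdb_id: str
    gene_symbols: list[str]
    protein_name: str = ""
    classes: frozenset[str] = frozenset()
    pocket_index: int | None = None


@dataclass
class PocketAnnotation:
    """pocket_id -> PocketRecord mapping with a declared class vocabulary."""

    records: dict[str, PocketRecord]
    class_vocabulary: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.class_vocabulary is not None:
            for rec in self.records.values():
                bad = rec.classes - self.class_vocabulary
                if bad:
                    raise ValueError(
                        f"pocket {rec.pocket_id!r} carries classes {sorted(bad)} "
                        f"outside the declared vocabulary"
                    )

    def __getitem__(self, pocket_id: str) -> PocketRecord:
        return self.records[pocket_id]

    def __contains__(self, pocket_id: str) -> bool:
        return pocket_id in self.records

    def pockets_in_class(self, class_tag: str) -> set[str]:
        return {p for p, r in self.records.items() if class_tag in r.classes}

    def genes_of(self, pocket_ids: Iterable[str]) -> set[str]:
        out: set[str] = set()
        for p in pocket_ids:
            if p in self.records:
                out.update(self.records[p].gene_symbols)
        return out


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty set of gene symbols (GMT semantics)."""

    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class ProbeGeneMap:
    """probe_id -> gene symbol; many probes may map to one gene."""

    probe_to_gene: dict[str, str]

    def genes(self) -> set[str]:
        return set(self.probe_to_gene.values())

    def probes_for(self, gene: str) -> list[str]:
        return [p for p, g in self.probe_to_gene.items() if g == gene]

    def gene_to_probes(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for probe, gene in self.probe_to_gene.items():
            out.setdefault(gene, []).append(probe)
        return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_tsv_lines(path: str | Path) -> list[list[str]]:
    text = Path(path).read_text(encoding="utf-8")
    rows = [line.split("\t") for line in text.splitlines() if line != ""]
    return rows


def read_score_matrix(
    path: str | Path,
    missing_token: str = DEFAULT_MISSING_TOKEN,
    transpose: bool = False,
    cls: type[ScoreMatrix] = ScoreMatrix,
) -> ScoreMatrix:
    """Read a pockets x drugs score TSV.

    Layout: header row of drug ids (first header cell ignored), first column
    pocket ids.  Cells equal to ``missing_token`` or blank are masked.
    ``transpose=True`` reads a drugs x pockets file instead.
    """
    rows = _read_tsv_lines(path)
    if not rows:
        raise ValueError(f"{path}: no header")
    header = rows[0]
    col_ids = [c.strip() for c in header[1:]]
    width = len(header)
    row_ids: list[str] = []
    data: list[list[float]] = []
    mask: list[list[bool]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ValueError(
                f"{path}: ragged row at line {lineno} "
                f"({len(row)} fields, expected {width})"
            )
        row_ids.append(row[0].strip())
        vals, miss = [], []
        for cell in row[1:]:
            cell = cell.strip()
            if cell == missing_token or cell == "":
                vals.append(np.nan)
                miss.append(True)
            else:
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}: unparseable value {cell!r} at line {lineno}"
                    ) from None
                miss.append(False)
        data.append(vals)
        mask.append(miss)
    values = np.array(data, dtype=float).reshape(len(row_ids), len(col_ids))
    missing = np.array(mask, dtype=bool).reshape(values.shape)
    if transpose:
        return cls(
            drug_ids=row_ids, pocket_ids=col_ids,
            values=values.T, missing=missing.T,
        )
    return cls(
        drug_ids=col_ids, pocket_ids=row_ids, values=values, missing=missing
    )


def write_score_matrix(
    m: ScoreMatrix,
    path: str | Path,
    missing_token: str = DEFAULT_MISSING_TOKEN,
) -> None:
    """Write a ScoreMatrix as TSV; finite values round-trip bit-identically."""
    buf = io.StringIO()
    buf.write("pocket_id\t" + "\t".join(m.drug_ids) + "\n")
    for i, pid in enumerate(m.pocket_ids):
        cells = [pid]
        for j in range(m.n_drugs):
            cells.append(missing_token if m.missing[i, j] else repr(float(m.values[i, j])))
        buf.write("\t".join(cells) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def _header_index(header: list[str], required: Sequence[str], path) -> dict[str, int]:
    idx = {name.strip(): i for i, name in enumerate(header)}
    for col in required:
        if col not in idx:
            raise ValueError(f"{path}: missing required column {col!r}")
    return idx


def read_roster(path: str | Path) -> DrugRoster:
    """Read a roster TSV with columns drug_id, role[, variant_group]."""
    rows = _read_tsv_lines(path)
    if not rows:
        raise ValueError(f"{path}: no header")
    idx = _header_index(rows[0], ["drug_id", "role"], path)
    has_group = "variant_group" in idx
    roles: dict[str, str] = {}
    groups: dict[str, str] = {}
    for lineno, row in enumerate(rows[1:], start=2):
        drug = row[idx["drug_id"]].strip()
        role = row[idx["role"]].strip()
        if drug in roles:
            raise ValueError(f"{path}: duplicate drug id {drug!r} at line {lineno}")
        if role not in Roles:
            raise ValueError(
                f"{path}: unknown role {role!r} at line {lineno}; "
                f"allowed roles: {', '.join(Roles)}"
            )
        roles[drug] = role
        if has_group and len(row) > idx["variant_group"]:
            grp = row[idx["variant_group"]].strip()
            if grp:
                groups[drug] = grp
    return DrugRoster(roles=roles, variant_groups=groups)


def write_roster(roster: DrugRoster, path: str | Path) -> None:
    lines = ["drug_id\trole\tvariant_group"]
    for drug, role in roster.roles.items():
        lines.append(f"{drug}\t{role}\t{roster.variant_groups.get(drug, '')}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_annotations(
    path: str | Path, class_vocabulary: Iterable[str] | None = None
) -> PocketAnnotation:
    """Read pocket annotations: pocket_id, pdb_id, genes, classes[, protein_name].

    ``genes`` and ``classes`` are comma- or pipe-separated lists.
    """
    rows = _read_tsv_lines(path)
    if not rows:
        raise ValueError(f"{path}: no header")
    idx = _header_index(rows[0], ["pocket_id", "pdb_id", "genes"], path)
    records: dict[str, PocketRecord] = {}
    for lineno, row in enumerate(rows[1:], start=2):
        pid = row[idx["pocket_id"]].strip()
        if pid in records:
            raise ValueError(f"{path}: duplicate pocket id {pid!r} at line {lineno}")
        genes = [
            g.strip()
            for g in row[idx["genes"]].replace("|", ",").split(",")
            if g.strip()
        ]
        classes: frozenset[str] = frozenset()
        if "classes" in idx and len(row) > idx["classes"]:
            classes = frozenset(
                c.strip()
                for c in row[idx["classes"]].replace("|", ",").split(",")
                if c.strip()
            )
        name = ""
        if "protein_name" in idx and len(row) > idx["protein_name"]:
            name = row[idx["protein_name"]].strip()
        records[pid] = PocketRecord(
            pocket_id=pid,
            pdb_id=row[idx["pdb_id"]].strip(),
            gene_symbols=genes,
            protein_name=name,
            classes=classes,
        )
    vocab = frozenset(class_vocabulary) if class_vocabulary is not None else None
    return PocketAnnotation(records=records, class_vocabulary=vocab)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets in standard GMT format (name, description, members...)."""
    sets: list[GeneSet] = []
    seen: set[str] = set()
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}: GMT line {lineno} has {len(fields)} fields; "
                "need name, description and at least one gene"
            )
        name, desc = fields[0].strip(), fields[1].strip()
        if name in seen:
            raise ValueError(f"{path}: duplicate gene set name {name!r}")
        seen.add(name)
        genes = frozenset(g.strip() for g in fields[2:] if g.strip())
        sets.append(GeneSet(name=name, genes=genes, description=desc))
    return sets


def read_probe_map(path: str | Path) -> ProbeGeneMap:
    """Read a probe->gene TSV with columns probe_id, gene."""
    rows = _read_tsv_lines(path)
    if not rows:
        raise ValueError(f"{path}: no header")
    idx = _header_index(rows[0], ["probe_id", "gene"], path)
    mapping: dict[str, str] = {}
    for lineno, row in enumerate(rows[1:], start=2):
        probe = row[idx["probe_id"]].strip()
        gene = row[idx["gene"]].strip()
        if probe in mapping:
            raise ValueError(f"{path}: duplicate probe id {probe!r} at line {lineno}")
        if not gene:
            raise ValueError(f"{path}: probe {probe!r} maps to no gene (line {lineno})")
        mapping[probe] = gene
    return ProbeGeneMap(probe_to_gene=mapping)
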