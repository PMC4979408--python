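"""Readers and writers for the external file formats of the pipeline.

Expression data follow the Broad/GSEA conventions: GCT v1.2 matrices, CLS
phenotype files, CHIP probe-to-symbol maps and GMT gene-set collections.
The remaining inputs are plain UTF-8, tab-delimited tables: a compound
structure table, ChEMBL-style bioactivity triples and CTD-style
disease-gene links.  Readers are strict (declared dimensions are checked,
bad cells are located) and every tabular reader reports how many rows it
rejected, so accepted + rejected always equals the row count of the file.

Only GCT v1.2 ("#1.2") is supported; v1.3 files are rejected with an
explicit message.  CLS assignment lines may use class indices or class
names; both resolve identically against the "#" label line.  Affinities
are canonicalized to nM at read time so that all downstream threshold
comparisons happen in a single unit.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .errors import (
    CellParseError,
    DimensionError,
    FormatError,
    ProbeConflictError,
    ValidationError,
)

__all__ = [
    "ExpressionProfile",
    "PhenotypeAssignment",
    "ProbeMap",
    "CompoundRecord",
    "BioactivityTriple",
    "DiseaseGeneLink",
    "GmtReadResult",
    "TableReadResult",
    "read_gct",
    "write_gct",
    "read_cls",
    "write_cls",
    "read_chip",
    "write_chip",
    "read_gmt",
    "write_gmt",
    "read_compounds",
    "write_compounds",
    "read_bioactivities",
    "write_bioactivities",
    "read_disease_links",
    "write_disease_links",
    "read_gene_protein_map",
    "write_gene_protein_map",
]

# placeholder gene symbols treated as unmapped in CHIP files
_NULL_SYMBOLS = {"", "---", "NA", "null"}


def _fmt(value: float) -> str:
    """Shortest decimal string that round-trips the float."""
    return repr(float(value))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionProfile:
    """A probes-x-samples expression matrix in the units of the source file."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    descriptions: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if self.descriptions is not None and len(self.descriptions) != len(self.probe_ids):
            raise ValidationError("descriptions length does not match probe count")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class PhenotypeAssignment:
    """Per-sample class membership from a CLS file."""

    class_labels: list[str]
    assignment: list[int]

    def __post_init__(self) -> None:
        if len(self.class_labels) < 2:
            raise ValidationError("at least 2 class labels required")
        if any(a < 0 or a >= len(self.class_labels) for a in self.assignment):
            raise ValidationError("assignment index out of range")

    @property
    def n_samples(self) -> int:
        return len(self.assignment)

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    def samples_in_class(self, index: int) -> list[int]:
        return [i for i, a in enumerate(self.assignment) if a == index]


@dataclass
class ProbeMap:
    """probe id -> gene symbol mapping (many probes may share a symbol)."""

    mapping: dict[str, str]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if any(not s for s in self.mapping.values()):
            raise ValidationError("empty gene symbol in probe map")

    def __len__(self) -> int:
        return len(self.mapping)

    def get(self, probe_id: str) -> str | None:
        return self.mapping.get(probe_id)


@dataclass
class CompoundRecord:
    compound_id: str
    instance_id: str
    structure: str | None  # SMILES; None marks a structureless record
    cell_line: str = ""
    therapeutic_flag: bool = False

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValidationError("compound_id must be non-empty")


@dataclass(frozen=True)
class BioactivityTriple:
    """One measured compound-target activity, affinity in nM."""

    compound_id: str
    structure: str
    target_id: str
    affinity_nM: float
    confidence_level: int

    def __post_init__(self) -> None:
        if not self.affinity_nM > 0:
            raise ValidationError(f"affinity must be positive, got {self.affinity_nM}")
        if not 0 <= self.confidence_level <= 10:
            raise ValidationError(
                f"confidence level must be in [0, 10], got {self.confidence_level}"
            )


@dataclass(frozen=True)
class DiseaseGeneLink:
    """A CTD-style gene-disease association with a text-mining inference score."""

    gene_symbol: str
    disease_id: str
    inference_score: float
    score_missing: bool = False  # True when the source row had an empty score

    def __post_init__(self) -> None:
        if self.inference_score < 0:
            raise ValidationError("inference score must be non-negative")


class GmtReadResult(NamedTuple):
    signatures: list  # list[GeneSignature]; typed loosely to avoid a cycle
    orphans: list[str]  # set names lacking their _UP/_DN partner


@dataclass
class TableReadResult:
    """Rows accepted by a tabular reader plus a tally of rejections."""

    records: list
    n_rejected: int = 0
    rejection_reasons: Counter = field(default_factory=Counter)
    n_flagged: int = 0  # rows accepted with a default substituted

    @property
    def n_total(self) -> int:
        return len(self.records) + self.n_rejected


# ---------------------------------------------------------------------------
# GCT v1.2
# ---------------------------------------------------------------------------


def read_gct(path: str | Path) -> ExpressionProfile:
    """Read a GCT v1.2 expression matrix, preserving row and column order."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].startswith("#"):
        raise FormatError(f"{path}: missing GCT version tag on line 1")
    version = lines[0].strip()
    if version != "#1.2":
        raise FormatError(
            f"{path}: unsupported GCT version {version!r}; only '#1.2' is supported"
        )
    if len(lines) < 3:
        raise FormatError(f"{path}: truncated GCT file")
    try:
        n_rows, n_cols = (int(t) for t in lines[1].split())
    except ValueError as exc:
        raise FormatError(f"{path}: bad dimension line {lines[1]!r}") from exc
    header = lines[2].split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: GCT header must start with NAME and Description")
    sample_ids = header[2:]
    if len(sample_ids) != n_cols:
        raise DimensionError(
            f"{path}: header declares {len(sample_ids)} samples, expected {n_cols}"
        )
    data_lines = [ln for ln in lines[3:] if ln.strip()]
    if len(data_lines) != n_rows:
        raise DimensionError(
            f"{path}: expected {n_rows} data rows, found {len(data_lines)}"
        )
    probe_ids: list[str] = []
    descriptions: list[str] = []
    values = np.empty((n_rows, n_cols), dtype=float)
    for i, line in enumerate(data_lines):
        fields = line.split("\t")
        if len(fields) != n_cols + 2:
            raise DimensionError(
                f"{path}: row {i + 1} has {len(fields) - 2} values, expected {n_cols}"
            )
        probe_ids.append(fields[0])
        descriptions.append(fields[1])
        for j, cell in enumerate(fields[2:]):
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise CellParseError(
                    f"{path}: non-numeric cell {cell!r} at data row {i + 1}, "
                    f"sample column {j + 1}",
                    row=i + 1,
                    column=j + 1,
                ) from None
    return ExpressionProfile(probe_ids, sample_ids, values, descriptions)


def write_gct(profile: ExpressionProfile, path: str | Path) -> None:
    descs = profile.descriptions or ["na"] * profile.n_probes
    out = ["#1.2", f"{profile.n_probes}\t{profile.n_samples}"]
    out.append("\t".join(["NAME", "Description", *profile.sample_ids]))
    for i, probe in enumerate(profile.probe_ids):
        row = [probe, descs[i], *(_fmt(v) for v in profile.values[i])]
        out.append("\t".join(row))
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# CLS
# ---------------------------------------------------------------------------


def read_cls(path: str | Path) -> PhenotypeAssignment:
    """Read a categorical CLS phenotype file.

    The third line may give per-sample class indices (``0 0 1 1``) or class
    names; names are resolved by exact match against the ``#`` label line.
    """
    lines = [ln for ln in Path(path).read_text(encoding="utf-8").splitlines() if ln.strip()]
    if len(lines) < 3:
        raise FormatError(f"{path}: CLS requires 3 lines")
    head = lines[0].split()
    if len(head) != 3:
        raise FormatError(f"{path}: bad CLS header {lines[0]!r}")
    try:
        n_samples, n_classes = int(head[0]), int(head[1])
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer CLS header {lines[0]!r}") from exc
    if not lines[1].startswith("#"):
        raise FormatError(f"{path}: CLS line 2 must start with '#'")
    labels = lines[1][1:].split()
    if len(labels) != n_classes:
        raise FormatError(
            f"{path}: header declares {n_classes} classes, label line has {len(labels)}"
        )
    tokens = lines[2].split()
    if len(tokens) != n_samples:
        raise FormatError(
            f"{path}: header declares {n_samples} samples, "
            f"assignment line has {len(tokens)} tokens"
        )
    by_name = {name: i for i, name in enumerate(labels)}
    assignment: list[int] = []
    for tok in tokens:
        if tok in by_name:
            assignment.append(by_name[tok])
        else:
            try:
                idx = int(tok)
            except ValueError:
                raise FormatError(
                    f"{path}: assignment token {tok!r} is neither a class index "
                    f"nor a declared class name"
                ) from None
            if not 0 <= idx < n_classes:
                raise FormatError(f"{path}: class index {idx} out of range")
            assignment.append(idx)
    return PhenotypeAssignment(labels, assignment)


def write_cls(phen: PhenotypeAssignment, path: str | Path) -> None:
    out = [
        f"{phen.n_samples} {phen.n_classes} 1",
        "# " + " ".join(phen.class_labels),
        " ".join(str(a) for a in phen.assignment),
    ]
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# CHIP
# ---------------------------------------------------------------------------


def read_chip(path: str | Path) -> ProbeMap:
    """Read a tab-delimited CHIP probe annotation file.

    Rows whose gene symbol is empty or a placeholder ("---") are dropped and
    counted in ``n_dropped``.  A probe id appearing twice with the same
    symbol is accepted; with conflicting symbols it is an error.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise FormatError(f"{path}: empty CHIP file")
    header = lines[0].split("\t")
    try:
        probe_col = header.index("Probe Set ID")
        symbol_col = header.index("Gene Symbol")
    except ValueError:
        raise FormatError(
            f"{path}: CHIP header must contain 'Probe Set ID' and 'Gene Symbol' columns"
        ) from None
    mapping: dict[str, str] = {}
    n_dropped = 0
    for line in lines[1:]:
        if not line.strip():
            continue
        fields = line.split("\t")
        probe = fields[probe_col]
        symbol = fields[symbol_col].strip() if len(fields) > symbol_col else ""
        if symbol in _NULL_SYMBOLS:
            n_dropped += 1
            continue
        if probe in mapping and mapping[probe] != symbol:
            raise ProbeConflictError(
                f"{path}: probe {probe!r} maps to both "
                f"{mapping[probe]!r} and {symbol!r}"
            )
        mapping[probe] = symbol
    return ProbeMap(mapping, n_dropped=n_dropped)


def write_chip(probe_map: ProbeMap, path: str | Path) -> None:
    out = ["Probe Set ID\tGene Symbol"]
    for probe, symbol in probe_map.mapping.items():
        out.append(f"{probe}\t{symbol}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# GMT (paired _UP/_DN signature sets)
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GmtReadResult:
    """Read paired up/down gene signatures from a GMT file.

    Sets are named ``<instance>_UP`` and ``<instance>_DN``; an instance with
    only one member of the pair is excluded and listed under ``orphans``.
    Duplicate genes inside one set are deduplicated with a warning.
    """
    from .signatures import GeneSignature  # local import avoids a module cycle

    raw: dict[str, list[str]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}: GMT line needs name, description and >=1 gene")
        name, genes = fields[0], fields[2:]
        deduped = list(dict.fromkeys(g for g in genes if g))
        if len(deduped) < len([g for g in genes if g]):
            warnings.warn(
                f"{path}: duplicate genes in set {name!r} removed "
                f"({len(genes) - len(deduped)} duplicates)",
                stacklevel=2,
            )
        raw[name] = deduped
    instances: dict[str, dict[str, list[str]]] = {}
    for name, genes in raw.items():
        for suffix, side in (("_UP", "up"), ("_DN", "down")):
            if name.endswith(suffix):
                instances.setdefault(name[: -len(suffix)], {})[side] = genes
                break
        else:
            instances.setdefault(name, {})  # unpaired naming -> orphan
    signatures, orphans = [], []
    for instance, sides in sorted(instances.items()):
        if "up" in sides and "down" in sides:
            signatures.append(
                GeneSignature(
                    up_genes=tuple(sides["up"]),
                    down_genes=tuple(sides["down"]),
                    x=max(len(sides["up"]), len(sides["down"])),
                    source_id=instance,
                )
            )
        else:
            orphans.append(instance)
            warnings.warn(
                f"{path}: instance {instance!r} lacks a complete _UP/_DN pair; excluded",
                stacklevel=2,
            )
    return GmtReadResult(signatures, orphans)


def write_gmt(signatures, path: str | Path) -> None:
    out = []
    for sig in signatures:
        out.append("\t".join([f"{sig.source_id}_UP", "na", *sig.up_genes]))
        out.append("\t".join([f"{sig.source_id}_DN", "na", *sig.down_genes]))
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# tabular TSVs
# ---------------------------------------------------------------------------


def _read_tsv_rows(path: str | Path, required: list[str]) -> tuple[list[str], list[list[str]]]:
    lines = [ln for ln in Path(path).read_text(encoding="utf-8").splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty table")
    header = lines[0].split("\t")
    missing = [c for c in required if c not in header]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return header, [ln.split("\t") for ln in lines[1:]]


def _cell(fields: list[str], header: list[str], column: str) -> str:
    idx = header.index(column)
    return fields[idx] if idx < len(fields) else ""


def read_compounds(path: str | Path) -> TableReadResult:
    """Read the compound structure table (one row per treatment instance)."""
    header, rows = _read_tsv_rows(
        path, ["compound_id", "instance_id", "smiles", "cell_line", "therapeutic_flag"]
    )
    result = TableReadResult(records=[])
    for fields in rows:
        smiles = _cell(fields, header, "smiles").strip()
        flag = _cell(fields, header, "therapeutic_flag").strip().lower()
        result.records.append(
            CompoundRecord(
                compound_id=_cell(fields, header, "compound_id"),
                instance_id=_cell(fields, header, "instance_id"),
                structure=smiles or None,
                cell_line=_cell(fields, header, "cell_line"),
                therapeutic_flag=flag in {"1", "true", "yes"},
            )
        )
    return result


def write_compounds(records: list[CompoundRecord], path: str | Path) -> None:
    out = ["compound_id\tinstance_id\tsmiles\tcell_line\ttherapeutic_flag"]
    for r in records:
        out.append(
            "\t".join(
                [
                    r.compound_id,
                    r.instance_id,
                    r.structure or "",
                    r.cell_line,
                    "1" if r.therapeutic_flag else "0",
                ]
            )
        )
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


_UNIT_TO_NM = {"nm": 1.0, "um": 1e3, "μm": 1e3, "µm": 1e3, "mm": 1e6}


def read_bioactivities(path: str | Path) -> TableReadResult:
    """Read bioactivity triples, canonicalizing affinities to nM.

    The affinity may be given directly in a column named ``affinity_nM`` or
    as a value column ``affinity`` plus a unit column ``unit`` (nM, uM/mM
    accepted).  Rows with non-positive affinities, unknown units or
    out-of-range confidence levels are rejected and tallied by reason.
    """
    header, rows = _read_tsv_rows(path, ["compound_id", "smiles", "target_id"])
    has_direct = "affinity_nM" in header
    if not has_direct and not ("affinity" in header and "unit" in header):
        raise FormatError(
            f"{path}: need an 'affinity_nM' column or 'affinity' + 'unit' columns"
        )
    conf_col = "confidence" if "confidence" in header else "confidence_level"
    if conf_col not in header:
        raise FormatError(f"{path}: missing confidence column")
    result = TableReadResult(records=[])

    def reject(reason: str) -> None:
        result.n_rejected += 1
        result.rejection_reasons[reason] += 1

    for fields in rows:
        if has_direct:
            raw, factor = _cell(fields, header, "affinity_nM"), 1.0
        else:
            raw = _cell(fields, header, "affinity")
            unit = _cell(fields, header, "unit").strip().lower()
            if unit not in _UNIT_TO_NM:
                reject("unknown_unit")
                continue
            factor = _UNIT_TO_NM[unit]
        try:
            affinity = float(raw) * factor
        except ValueError:
            reject("bad_affinity")
            continue
        if affinity <= 0:
            reject("nonpositive_affinity")
            continue
        try:
            confidence = int(_cell(fields, header, conf_col))
        except ValueError:
            reject("bad_confidence")
            continue
        if not 0 <= confidence <= 10:
            reject("confidence_out_of_range")
            continue
        result.records.append(
            BioactivityTriple(
                compound_id=_cell(fields, header, "compound_id"),
                structure=_cell(fields, header, "smiles"),
                target_id=_cell(fields, header, "target_id"),
                affinity_nM=affinity,
                confidence_level=confidence,
            )
        )
    return result


def write_bioactivities(triples: list[BioactivityTriple], path: str | Path) -> None:
    out = ["compound_id\tsmiles\ttarget_id\taffinity_nM\tconfidence"]
    for t in triples:
        out.append(
            "\t".join(
                [t.compound_id, t.structure, t.target_id, _fmt(t.affinity_nM), str(t.confidence_level)]
            )
        )
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def read_disease_links(path: str | Path) -> TableReadResult:
    """Read CTD-style gene-disease links with inference scores.

    Rows with an empty score are kept with score 0 and flagged
    (``score_missing``); rows with a negative score are rejected.
    """
    header, rows = _read_tsv_rows(path, ["gene_symbol", "disease_id", "inference_score"])
    result = TableReadResult(records=[])
    for fields in rows:
        raw = _cell(fields, header, "inference_score").strip()
        missing = raw == ""
        if missing:
            score = 0.0
            result.n_flagged += 1
        else:
            try:
                score = float(raw)
            except ValueError:
                result.n_rejected += 1
                result.rejection_reasons["bad_score"] += 1
                continue
            if score < 0:
                result.n_rejected += 1
                result.rejection_reasons["negative_score"] += 1
                continue
        result.records.append(
            DiseaseGeneLink(
                gene_symbol=_cell(fields, header, "gene_symbol"),
                disease_id=_cell(fields, header, "disease_id"),
                inference_score=score,
                score_missing=missing,
            )
        )
    return result


def write_disease_links(links: list[DiseaseGeneLink], path: str | Path) -> None:
    out = ["gene_symbol\tdisease_id\tinference_score"]
    for link in links:
        score = "" if link.score_missing else _fmt(link.inference_score)
        out.append(f"{link.gene_symbol}\t{link.disease_id}\t{score}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def read_gene_protein_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping protein target ids to gene symbols."""
    header, rows = _read_tsv_rows(path, ["target_id", "gene_symbol"])
    return {
        _cell(fields, header, "target_id"): _cell(fields, header, "gene_symbol")
        for fields in rows
    }


def write_gene_protein_map(mapping: dict[str, str], path: str | Path) -> None:
    out = ["target_id\tgene_symbol"]
    out += [f"{t}\t{g}" for t, g in mapping.items()]
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")
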