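"""Gene presence/absence matrices from ortholog loss-summary files.

TOGA (Tool to infer Orthologs from Genome Alignments) classifies every
reference gene in a query genome with a status code — intact ("I"),
clearly lost ("L"), uncertain loss ("UL"), partially intact ("PI"),
missing ("M"), and so on; the vocabulary drifts between releases, so the
parser accepts any token.  This module turns per-species ``loss_summ``
TSV files into a binary species × gene matrix: state 0 for a lost gene,
state 1 for everything else (the conservative coding — only the
highest-confidence losses count, at the price of missing very recent
pseudogenisation).  The loss-status set is configurable (add "UL"/"PI"
for a permissive coding).

The :class:`PresenceMatrix` produced here is the central object of the
package; it round-trips through TSV and NEXUS, and exports the classic
10-character PHYLIP discrete format for interop with discrete-character
phylogenetics programs.
"""

from __future__ import annotations

import fnmatch
import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TogaRecord",
    "PresenceMatrix",
    "Blacklist",
    "TogaParseError",
    "parse_toga_summary",
    "code_presence",
    "assemble_matrix",
    "filter_blacklist",
    "write_matrix",
    "read_matrix",
    "default_blacklist",
]

DEFAULT_LOSS_STATUSES = frozenset({"L"})


class TogaParseError(ValueError):
    pass


@dataclass(frozen=True)
class TogaRecord:
    """One line of a loss-summary file."""

    entry_class: str  # GENE, TRANSCRIPT or PROJECTION
    identifier: str
    status: str

    ENTRY_CLASSES = ("GENE", "TRANSCRIPT", "PROJECTION")

    def __post_init__(self):
        if self.entry_class not in self.ENTRY_CLASSES:
            raise ValueError(f"unknown entry class {self.entry_class!r}")
        if not self.identifier:
            raise ValueError("empty identifier")
        if not self.status:
            raise ValueError("empty status")

    @property
    def is_gene(self) -> bool:
        return self.entry_class == "GENE"


@dataclass
class PresenceMatrix:
    """Binary species × gene matrix; 1 = present, 0 = lost."""

    species: list[str]
    genes: list[str]
    states: np.ndarray  # shape (n_species, n_genes), int8 in {0, 1}

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (len(self.species), len(self.genes)):
            raise ValueError(
                f"states shape {self.states.shape} inconsistent with "
                f"{len(self.species)} species × {len(self.genes)} genes"
            )
        if len(set(self.species)) != len(self.species):
            raise ValueError("species labels must be unique")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene identifiers must be unique")
        bad = set(np.unique(self.states)) - {0, 1}
        if bad:
            raise ValueError(f"states must be 0/1, found {sorted(bad)}")

    # ----------------------------------------------------------- conversion
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.states, index=self.species, columns=self.genes)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PresenceMatrix":
        return cls(
            [str(s) for s in frame.index],
            [str(g) for g in frame.columns],
            frame.to_numpy(dtype=np.int8),
        )

    # ------------------------------------------------------------ selection
    def subset_genes(self, genes: Sequence[str]) -> "PresenceMatrix":
        idx = {g: j for j, g in enumerate(self.genes)}
        cols = [idx[g] for g in genes]
        return PresenceMatrix(list(self.species), list(genes), self.states[:, cols])

    def resample_genes(self, indices: Sequence[int]) -> "PresenceMatrix":
        """Column resample (bootstrap); gene names become positional."""
        indices = np.asarray(indices)
        names = [f"{self.genes[j]}~{i}" for i, j in enumerate(indices)]
        return PresenceMatrix(list(self.species), names, self.states[:, indices])

    def character(self, gene: str) -> dict[str, int]:
        j = self.genes.index(gene)
        return {s: int(self.states[i, j]) for i, s in enumerate(self.species)}

    def __eq__(self, other):
        return (
            isinstance(other, PresenceMatrix)
            and self.species == other.species
            and self.genes == other.genes
            and np.array_equal(self.states, other.states)
        )


@dataclass(frozen=True)
class Blacklist:
    """Gene families excluded for unreliable orthology assignment.

    Patterns are exact symbols or shell-style globs ("KRT*"), matched
    case-sensitively against gene identifiers.
    """

    patterns: tuple[str, ...]

    def __post_init__(self):
        if not self.patterns:
            raise ValueError("blacklist requested with no patterns")

    @classmethod
    def from_file(cls, path) -> "Blacklist":
        pats = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                pats.append(line)
        return cls(tuple(pats))

    def matches(self, gene: str) -> bool:
        return any(fnmatch.fnmatchcase(gene, p) for p in self.patterns)


def default_blacklist() -> Blacklist:
    """The packaged default family blacklist (uncharacterised ORFs,
    beta-defensins, FAM/histone/keratin/NPIP/PRAME/SLC/SPATA/USP/zinc-finger
    and UDP-glucuronosyltransferase families)."""
    from importlib.resources import files

    path = files("dolloloss").joinpath("data/blacklist_default.txt")
    pats = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    return Blacklist(tuple(pats))


# -------------------------------------------------------------------- parse


def parse_toga_summary(stream) -> list[TogaRecord]:
    """Parse a loss-summary stream (path, text, file object, or lines).

    Lines are tab-separated ``entry_class  identifier  status``; extra
    columns are ignored, blank and ``#`` lines skipped.  Non-GENE rows are
    retained (tagged by ``entry_class``) so downstream coding can ignore
    them.
    """
    lines = _as_lines(stream)
    records = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise TogaParseError(
                f"line {lineno}: expected >=3 tab-separated columns, got {len(parts)}"
            )
        try:
            records.append(TogaRecord(parts[0], parts[1], parts[2]))
        except ValueError as exc:
            raise TogaParseError(f"line {lineno}: {exc}") from exc
    return records


def _as_lines(stream) -> Iterable[str]:
    if isinstance(stream, (str, Path)):
        p = Path(stream)
        if isinstance(stream, Path) or (len(str(stream)) < 4096 and p.is_file()):
            return p.read_text().splitlines()
        return str(stream).splitlines()
    if isinstance(stream, io.TextIOBase):
        return stream.read().splitlines()
    return list(stream)


def code_presence(
    records: Iterable[TogaRecord],
    loss_statuses: Iterable[str] = DEFAULT_LOSS_STATUSES,
) -> dict[str, int]:
    """Binary-code GENE records: 0 iff status is in ``loss_statuses``.

    Duplicate gene rows with conflicting statuses resolve by "any loss ⇒ 0"
    and are reported as a warning, never an error.
    """
    loss = frozenset(loss_statuses)
    states: dict[str, int] = {}
    conflicts = set()
    for rec in records:
        if not rec.is_gene:
            continue
        value = 0 if rec.status in loss else 1
        if rec.identifier in states and states[rec.identifier] != value:
            conflicts.add(rec.identifier)
            value = 0  # any loss wins
        states[rec.identifier] = min(states.get(rec.identifier, 1), value)
    if conflicts:
        warnings.warn(
            f"{len(conflicts)} genes had conflicting duplicate statuses, "
            f"coded as lost: {sorted(conflicts)[:10]}",
            stacklevel=2,
        )
    return states


def assemble_matrix(
    per_species: Mapping[str, Mapping[str, int]],
    universe_policy: str = "union",
    fill_state: int = 1,
    reference_genes: Sequence[str] | None = None,
) -> PresenceMatrix:
    """Stack per-species gene→state maps into one matrix.

    ``universe_policy``: "union" (genes seen in any species; absences coded
    with ``fill_state``, default 1 — the likely-present collapse),
    "intersection" (genes seen in every species), or "reference-list"
    (an explicit gene universe via ``reference_genes``).
    """
    if len(per_species) < 2:
        raise ValueError("need at least two species")
    species = list(per_species)
    gene_sets = [set(m) for m in per_species.values()]
    if universe_policy == "union":
        universe = set().union(*gene_sets)
    elif universe_policy == "intersection":
        universe = set.intersection(*gene_sets)
    elif universe_policy == "reference-list":
        if reference_genes is None:
            raise ValueError("reference-list policy needs reference_genes")
        universe = set(reference_genes)
    else:
        raise ValueError(f"unknown universe policy {universe_policy!r}")
    if not universe:
        raise ValueError("empty gene universe under policy " + universe_policy)
    genes = sorted(universe)
    states = np.full((len(species), len(genes)), fill_state, dtype=np.int8)
    filled = 0
    for i, sp in enumerate(species):
        m = per_species[sp]
        for j, g in enumerate(genes):
            if g in m:
                states[i, j] = m[g]
            else:
                filled += 1
    if filled:
        logger.info(
            "assemble_matrix: %d absent cells filled with state %d", filled, fill_state
        )
    return PresenceMatrix(species, genes, states)


def filter_blacklist(matrix: PresenceMatrix, blacklist: Blacklist) -> PresenceMatrix:
    """Drop every gene matching any blacklist pattern."""
    keep = [g for g in matrix.genes if not blacklist.matches(g)]
    removed = len(matrix.genes) - len(keep)
    if removed:
        logger.info("filter_blacklist: removed %d genes", removed)
    if not keep:
        warnings.warn("blacklist removed every gene; matrix now has 0 genes",
                      stacklevel=2)
        return PresenceMatrix(
            list(matrix.species), [], np.zeros((len(matrix.species), 0), dtype=np.int8)
        )
    return matrix.subset_genes(keep)


# ---------------------------------------------------------------- matrix i/o

PHYLIP_NAME_WIDTH = 10


def write_matrix(matrix: PresenceMatrix, format: str = "tsv") -> str:
    """Serialise to "tsv", "nexus" or "phylip-discrete" text."""
    if format == "tsv":
        return matrix.to_frame().to_csv(sep="\t", index_label="species")
    if format == "phylip-discrete":
        return _write_phylip(matrix)
    if format == "nexus":
        return _write_nexus(matrix)
    raise ValueError(f"unknown matrix format {format!r}")


def read_matrix(text, format: str = "tsv") -> PresenceMatrix:
    """Read "tsv" or "nexus" text (or a path to one) back into a matrix."""
    if isinstance(text, Path) or (isinstance(text, str) and "\n" not in text
                                  and Path(text).is_file()):
        text = Path(text).read_text()
    if format == "tsv":
        frame = pd.read_csv(io.StringIO(text), sep="\t", index_col=0)
        return PresenceMatrix.from_frame(frame)
    if format == "nexus":
        return _read_nexus(text)
    raise ValueError(f"unknown matrix format {format!r}")


def _phylip_name(name: str) -> str:
    return name[:PHYLIP_NAME_WIDTH].ljust(PHYLIP_NAME_WIDTH)


def _write_phylip(matrix: PresenceMatrix) -> str:
    names = [_phylip_name(s) for s in matrix.species]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(
            "species names collide after 10-character truncation: "
            + ", ".join(sorted(n.strip() for n in dupes))
        )
    lines = [f"{len(matrix.species)} {len(matrix.genes)}"]
    for name, row in zip(names, matrix.states):
        lines.append(name + "".join(str(int(v)) for v in row))
    return "\n".join(lines) + "\n"


def _write_nexus(matrix: PresenceMatrix) -> str:
    out = io.StringIO()
    out.write("#NEXUS\n\nBEGIN DATA;\n")
    out.write(
        f"    DIMENSIONS NTAX={len(matrix.species)} NCHAR={len(matrix.genes)};\n"
    )
    out.write('    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;\n')
    out.write(
        "    CHARLABELS\n        "
        + " ".join(matrix.genes)
        + "\n    ;\n"
    )
    out.write("    MATRIX\n")
    width = max((len(s) for s in matrix.species), default=1) + 2
    for sp, row in zip(matrix.species, matrix.states):
        out.write(f"        {sp.ljust(width)}{''.join(str(int(v)) for v in row)}\n")
    out.write("    ;\nEND;\n")
    return out.getvalue()


def _read_nexus(text: str) -> PresenceMatrix:
    """Read a standard-datatype DATA block (as written by :func:`write_matrix`)."""
    import dendropy

    try:
        char = dendropy.StandardCharacterMatrix.get(
            data=text, schema="nexus", preserve_underscores=True
        )
    except Exception as exc:
        raise ValueError(f"could not parse NEXUS matrix: {exc}") from exc
    species = [t.label for t in char.taxon_namespace]
    rows = []
    for taxon in char.taxon_namespace:
        seq = char[taxon]
        rows.append([int(str(s)) for s in seq.symbols_as_list()])
    states = np.array(rows, dtype=np.int8)
    genes = _nexus_charlabels(text, states.shape[1])
    return PresenceMatrix(species, genes, states)


def _nexus_charlabels(text: str, n_chars: int) -> list[str]:
    upper = text.upper()
    start = upper.find("CHARLABELS")
    if start == -1:
        return [f"char{j+1}" for j in range(n_chars)]
    end = text.index(";", start)
    labels = text[start + len("CHARLABELS"): end].split()
    if len(labels) != n_chars:
        raise ValueError(
            f"CHARLABELS lists {len(labels)} names for {n_chars} characters"
        )
    return labels
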