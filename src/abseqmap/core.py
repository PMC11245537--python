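"""Domain types, AIRR-format I/O, and clonotype-level filters.

The pipeline starts from clonotype tables (post read-annotation): a
:class:`Clonotype` is one recombined receptor chain keyed by its CDR3
(nucleotide when available, else amino acid) together with the V gene,
J gene and isotype; a :class:`Repertoire` is a sample's clonotype
collection; single-cell data add :class:`CellRecord` (one droplet barcode
with exactly one heavy and one light chain) and
:class:`SingleCellRepertoire`, where clonotype sizes count distinct cell
barcodes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "AirrFormatError",
    "EmptyInputError",
    "Clonotype",
    "Repertoire",
    "CellRecord",
    "SingleCellRepertoire",
    "read_airr",
    "write_airr",
    "filter_productive",
    "filter_cells_one_heavy_one_light",
    "build_clonotypes",
    "export_reference_fasta",
    "read_reference_fasta",
    "translate_nt",
]

HEAVY = "heavy"
KAPPA = "kappa"
LAMBDA = "lambda"
CHAINS = (HEAVY, KAPPA, LAMBDA)
LIGHT_CHAINS = (KAPPA, LAMBDA)

ISOTYPES = ("IgA", "IgD", "IgG", "IgM", "none")

_LOCUS_TO_CHAIN = {"IGH": HEAVY, "IGK": KAPPA, "IGL": LAMBDA}
_CHAIN_TO_LOCUS = {v: k for k, v in _LOCUS_TO_CHAIN.items()}

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

_CODON_TO_AA = dict(standard_dna_table.forward_table)


class AirrFormatError(ValueError):
    """A required column is missing or a field cannot be interpreted."""


class EmptyInputError(ValueError):
    """The input file or table contains no usable records."""


def translate_nt(nt: str) -> str:
    """Standard-table translation of an in-frame DNA string (no stops expected)."""
    if len(nt) % 3 != 0:
        raise ValueError(f"sequence length {len(nt)} not divisible by 3")
    out = []
    for i in range(0, len(nt), 3):
        codon = nt[i : i + 3].upper()
        out.append(_CODON_TO_AA.get(codon, "*"))
    return "".join(out)


def strip_allele(call: str) -> str:
    """Collapse an IMGT-style gene call to gene level ('IGHV1-2*02' -> 'IGHV1-2').

    Only the first call is kept when multiple comma-separated calls are given.
    Alleles are not discriminated anywhere downstream.
    """
    first = call.split(",")[0].strip()
    return first.split("*")[0]


def isotype_from_c_call(c_call: str | None, chain: str) -> str:
    """Map a constant-region call to a coarse isotype label.

    Light chains carry no isotype (the IgK serum-fraction label used in
    proteomics sample metadata is not a clonotype isotype).
    """
    if chain != HEAVY or not c_call or not isinstance(c_call, str):
        return "none"
    c = strip_allele(c_call).upper()
    for letter, label in (("A", "IgA"), ("D", "IgD"), ("G", "IgG"), ("M", "IgM")):
        if c.startswith("IGH" + letter) or c == "IG" + letter or c.startswith("IGH" + letter.lower()):
            return label
    return "none"


@dataclass(frozen=True)
class Clonotype:
    """One recombined receptor chain.

    ``cdr3_span`` is a 0-based half-open interval into ``vdj_aa`` such that
    ``vdj_aa[start:end] == cdr3_aa``.
    """

    chain: str
    v_gene: str
    j_gene: str
    cdr3_aa: str
    vdj_aa: str
    cdr3_span: tuple[int, int]
    size: int = 1
    isotype: str = "none"
    cdr3_nt: str | None = None
    productive: bool = True

    def __post_init__(self):
        if self.chain not in CHAINS:
            raise ValueError(f"unknown chain {self.chain!r}")
        if self.size < 1:
            raise ValueError("clonotype size must be >= 1")
        start, end = self.cdr3_span
        if self.vdj_aa[start:end] != self.cdr3_aa:
            raise ValueError(
                f"cdr3_span {self.cdr3_span} does not slice cdr3_aa out of vdj_aa "
                f"({self.vdj_aa[start:end]!r} != {self.cdr3_aa!r})"
            )

    @property
    def clonotype_key(self) -> str:
        """Deterministic clonal identity: CDR3 (nt when present) + V + J + isotype."""
        cdr3 = self.cdr3_nt if self.cdr3_nt else self.cdr3_aa
        return f"{cdr3}_{self.v_gene}_{self.j_gene}_{self.isotype}"

    @property
    def aa_identity(self) -> tuple[str, str, str, str]:
        """Amino-acid-level clonal identity (chain, V, J, CDR3 aa).

        Peptide-level evidence cannot distinguish nucleotide variants, so
        uniqueness of peptide mapping is evaluated at this resolution.
        """
        return (self.chain, self.v_gene, self.j_gene, self.cdr3_aa)

    def nt_consistent(self) -> bool:
        """True when cdr3_nt, if present and in frame, translates to cdr3_aa."""
        if not self.cdr3_nt:
            return True
        if len(self.cdr3_nt) % 3 != 0:
            return False
        return translate_nt(self.cdr3_nt) == self.cdr3_aa


def _check_unique_keys(clonotypes: Sequence[Clonotype]) -> None:
    seen: set[str] = set()
    for ct in clonotypes:
        k = ct.clonotype_key
        if k in seen:
            raise ValueError(f"duplicate clonotype_key within repertoire: {k}")
        seen.add(k)


@dataclass
class Repertoire:
    """A sample's clonotype collection with donor/method metadata.

    Clonotype keys are unique within a repertoire. The clonal frequency
    distribution ``f`` (sizes normalised to sum 1) and the unique CDR3
    amino-acid set derive from the clonotype list.
    """

    sample_id: str
    donor: str
    method: str  # 'bulk' | 'single_cell'
    clonotypes: list[Clonotype]
    isotype_or_subset: str = ""
    replicate_id: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in ("bulk", "single_cell"):
            raise ValueError(f"unknown method {self.method!r}")
        _check_unique_keys(self.clonotypes)

    @property
    def n(self) -> int:
        return len(self.clonotypes)

    def sizes(self, chain: str | None = None):
        return [ct.size for ct in self.iter_chain(chain)]

    def frequencies(self, chain: str | None = None) -> list[float]:
        """Clonal frequency distribution f_i = size_i / sum(size)."""
        sizes = self.sizes(chain)
        total = sum(sizes)
        return [s / total for s in sizes]

    def iter_chain(self, chain: str | None = None) -> Iterable[Clonotype]:
        if chain is None:
            return iter(self.clonotypes)
        if chain == "light":
            return (c for c in self.clonotypes if c.chain in LIGHT_CHAINS)
        return (c for c in self.clonotypes if c.chain == chain)

    def cdr3_set(self, chain: str | None = HEAVY) -> set[str]:
        """Unique CDR3 amino-acid sequences (heavy chain / CDRH3 by default)."""
        return {c.cdr3_aa for c in self.iter_chain(chain)}


@dataclass(frozen=True)
class CellRecord:
    """One single-cell droplet: a barcode with exactly one heavy and one light chain."""

    cell_id: str
    heavy: Clonotype
    light: Clonotype

    def __post_init__(self):
        if self.heavy.chain != HEAVY:
            raise ValueError("CellRecord.heavy must be a heavy chain")
        if self.light.chain not in LIGHT_CHAINS:
            raise ValueError("CellRecord.light must be a kappa or lambda chain")


@dataclass
class SingleCellRepertoire(Repertoire):
    """Paired-chain repertoire; clonotype sizes count distinct cell barcodes."""

    cells: list[CellRecord] = field(default_factory=list)
    barcodes: dict[str, frozenset] = field(default_factory=dict)  # clonotype_key -> barcode set

    @classmethod
    def from_cells(
        cls,
        cells: Sequence[CellRecord],
        sample_id: str,
        donor: str,
        isotype_or_subset: str = "",
        replicate_id: str | None = None,
        metadata: dict | None = None,
    ) -> "SingleCellRepertoire":
        """Aggregate cell records into clonotypes sized by distinct barcodes."""
        barcode_map: dict[str, set] = {}
        proto: dict[str, Clonotype] = {}
        for cell in cells:
            for ct in (cell.heavy, cell.light):
                key = ct.clonotype_key
                barcode_map.setdefault(key, set()).add(cell.cell_id)
                proto.setdefault(key, ct)
        clonotypes = [
            replace(proto[key], size=len(bcs)) for key, bcs in barcode_map.items()
        ]
        clonotypes.sort(key=lambda c: (-c.size, c.clonotype_key))
        return cls(
            sample_id=sample_id,
            donor=donor,
            method="single_cell",
            clonotypes=clonotypes,
            isotype_or_subset=isotype_or_subset,
            replicate_id=replicate_id,
            metadata=metadata or {},
            cells=list(cells),
            barcodes={k: frozenset(v) for k, v in barcode_map.items()},
        )

    def heavy_clonotypes(self) -> list[Clonotype]:
        return [c for c in self.clonotypes if c.chain == HEAVY]

    def light_clonotypes(self) -> list[Clonotype]:
        return [c for c in self.clonotypes if c.chain in LIGHT_CHAINS]


# ---------------------------------------------------------------------------
# AIRR Rearrangement I/O
# ---------------------------------------------------------------------------

REQUIRED_AIRR_COLUMNS = ("v_call", "j_call", "junction_aa", "locus")

#: columns written by write_airr and understood by read_airr
AIRR_COLUMNS = (
    "sequence_id",
    "v_call",
    "j_call",
    "c_call",
    "locus",
    "junction",
    "junction_aa",
    "sequence_alignment_aa",
    "duplicate_count",
    "cell_id",
    "productive",
)


def _row_to_clonotype(row: pd.Series) -> Clonotype:
    locus = str(row["locus"]).strip()
    if locus not in _LOCUS_TO_CHAIN:
        raise AirrFormatError(f"unknown locus {locus!r}")
    chain = _LOCUS_TO_CHAIN[locus]
    cdr3_aa = str(row["junction_aa"])
    vdj_aa = row.get("sequence_alignment_aa")
    if not isinstance(vdj_aa, str) or not vdj_aa:
        vdj_aa = cdr3_aa
    start = vdj_aa.find(cdr3_aa)
    if start < 0:
        raise AirrFormatError(
            f"junction_aa {cdr3_aa!r} not found in sequence_alignment_aa"
        )
    junction = row.get("junction")
    cdr3_nt = junction if isinstance(junction, str) and junction else None
    size = row.get("duplicate_count")
    size = int(size) if pd.notna(size) else 1
    productive = row.get("productive")
    if isinstance(productive, str):
        productive = productive.strip().upper() in ("T", "TRUE", "1", "YES")
    elif pd.isna(productive):
        productive = True
    return Clonotype(
        chain=chain,
        v_gene=strip_allele(str(row["v_call"])),
        j_gene=strip_allele(str(row["j_call"])),
        isotype=isotype_from_c_call(row.get("c_call"), chain),
        cdr3_aa=cdr3_aa,
        vdj_aa=vdj_aa,
        cdr3_span=(start, start + len(cdr3_aa)),
        size=max(size, 1),
        cdr3_nt=cdr3_nt,
        productive=bool(productive),
    )


def _read_airr_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"empty AIRR file: {path}") from None
    for col in REQUIRED_AIRR_COLUMNS:
        if col not in df.columns:
            raise AirrFormatError(f"missing required AIRR column: {col}")
    if len(df) == 0:
        raise EmptyInputError(f"no records in AIRR file: {path}")
    return df


def read_airr(
    path,
    method: str,
    donor: str = "donor",
    sample_id: str | None = None,
    isotype_or_subset: str = "",
):
    """Read an AIRR Rearrangement TSV into Repertoire(s).

    Allele suffixes on v_call/j_call are stripped to gene level. When a
    ``sample_id`` column is present, one repertoire per sample is returned
    as a list; otherwise a single repertoire. For ``method='single_cell'``
    rows are grouped by ``cell_id`` into cells and filtered to exactly one
    heavy plus one light chain per cell.
    """
    df = _read_airr_table(path)
    if "sample_id" in df.columns:
        out = []
        for sid, sub in df.groupby("sample_id", sort=True):
            out.append(
                _rows_to_repertoire(sub, method, donor, str(sid), isotype_or_subset)
            )
        return out
    sid = sample_id or (Path(path).stem if not isinstance(path, io.IOBase) else "sample")
    return _rows_to_repertoire(df, method, donor, sid, isotype_or_subset)


def _rows_to_repertoire(df, method, donor, sample_id, isotype_or_subset):
    if method == "single_cell":
        return filter_cells_one_heavy_one_light(
            df, sample_id=sample_id, donor=donor, isotype_or_subset=isotype_or_subset
        )
    clonotypes: dict[str, Clonotype] = {}
    for _, row in df.iterrows():
        ct = _row_to_clonotype(row)
        prev = clonotypes.get(ct.clonotype_key)
        if prev is not None:
            ct = replace(prev, size=prev.size + ct.size)
        clonotypes[ct.clonotype_key] = ct
    cts = sorted(clonotypes.values(), key=lambda c: (-c.size, c.clonotype_key))
    return Repertoire(
        sample_id=sample_id,
        donor=donor,
        method="bulk",
        clonotypes=cts,
        isotype_or_subset=isotype_or_subset,
    )


def write_airr(rep: Repertoire, path) -> None:
    """Write a repertoire as an AIRR Rearrangement TSV (supported column subset)."""
    rows = []

    def _ct_row(ct: Clonotype, seq_id: str, cell_id: str | None, count: int | None):
        return {
            "sequence_id": seq_id,
            "v_call": ct.v_gene,
            "j_call": ct.j_gene,
            "c_call": "" if ct.isotype == "none" else "IGH" + ct.isotype[-1],
            "locus": _CHAIN_TO_LOCUS[ct.chain],
            "junction": ct.cdr3_nt or "",
            "junction_aa": ct.cdr3_aa,
            "sequence_alignment_aa": ct.vdj_aa,
            "duplicate_count": count,
            "cell_id": cell_id or "",
            "productive": "T" if ct.productive else "F",
        }

    if isinstance(rep, SingleCellRepertoire):
        i = 0
        for cell in rep.cells:
            for ct in (cell.heavy, cell.light):
                rows.append(_ct_row(ct, f"seq{i}", cell.cell_id, None))
                i += 1
    else:
        for i, ct in enumerate(rep.clonotypes):
            rows.append(_ct_row(ct, f"seq{i}", None, ct.size))
    pd.DataFrame(rows, columns=AIRR_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def is_productive(ct: Clonotype) -> bool:
    """Productive = annotated productive, no internal stop, CDR3 nt in frame."""
    if not ct.productive:
        return False
    if "*" in ct.vdj_aa:
        return False
    if ct.cdr3_nt is not None and len(ct.cdr3_nt) % 3 != 0:
        return False
    return True


def filter_productive(rep: Repertoire) -> Repertoire:
    """Remove out-of-frame and stop-containing clonotypes. Idempotent."""
    kept = [ct for ct in rep.clonotypes if is_productive(ct)]
    out = replace(rep, clonotypes=kept)
    return out


def filter_cells_one_heavy_one_light(
    records: pd.DataFrame,
    sample_id: str = "sample",
    donor: str = "donor",
    isotype_or_subset: str = "",
    replicate_id: str | None = None,
) -> SingleCellRepertoire:
    """Keep cells with exactly one heavy and one light chain.

    ``records`` is a raw per-cell chain table in AIRR dialect with at least
    cell_id and locus; surviving cells become CellRecords and clonotype
    sizes are recomputed from distinct barcodes.
    """
    if "cell_id" not in records.columns:
        raise AirrFormatError("missing required AIRR column: cell_id")
    if "locus" not in records.columns:
        raise AirrFormatError("missing required AIRR column: locus")
    cells: list[CellRecord] = []
    for cell_id, sub in records.groupby("cell_id", sort=True):
        if not isinstance(cell_id, str) or not cell_id:
            continue
        heavies, lights = [], []
        for _, row in sub.iterrows():
            ct = _row_to_clonotype(row)
            (heavies if ct.chain == HEAVY else lights).append(ct)
        if len(heavies) == 1 and len(lights) == 1:
            cells.append(CellRecord(cell_id=cell_id, heavy=heavies[0], light=lights[0]))
    return SingleCellRepertoire.from_cells(
        cells,
        sample_id=sample_id,
        donor=donor,
        isotype_or_subset=isotype_or_subset,
        replicate_id=replicate_id,
    )


def build_clonotypes(rows: pd.DataFrame, method: str, **rep_kwargs) -> Repertoire:
    """Group annotated rows into clonotypes sized by distinct UMIs or barcodes.

    Bulk rows must carry a ``umi`` column; single-cell rows a ``cell_id``
    column. Clonal count is the number of distinct UMIs (bulk) or cell
    barcodes (single-cell) observed for each clonotype key. Output order is
    deterministic: descending size, then key.
    """
    tag_col = "umi" if method == "bulk" else "cell_id"
    if tag_col not in rows.columns:
        raise AirrFormatError(f"missing required column for {method} counting: {tag_col}")
    tags: dict[str, set] = {}
    proto: dict[str, Clonotype] = {}
    for _, row in rows.iterrows():
        ct = _row_to_clonotype(row)
        key = ct.clonotype_key
        tags.setdefault(key, set()).add(row[tag_col])
        proto.setdefault(key, ct)
    cts = [replace(proto[k], size=len(v)) for k, v in tags.items()]
    cts.sort(key=lambda c: (-c.size, c.clonotype_key))
    rep_kwargs.setdefault("sample_id", "sample")
    rep_kwargs.setdefault("donor", "donor")
    return Repertoire(method=method, clonotypes=cts, **rep_kwargs)


# ---------------------------------------------------------------------------
# Reference FASTA export
# ---------------------------------------------------------------------------

def _fasta_header(ct: Clonotype, rep: Repertoire) -> str:
    s, e = ct.cdr3_span
    return "|".join(
        [ct.clonotype_key, rep.sample_id, ct.chain, rep.method, f"{s}-{e}",
         ct.isotype, str(ct.size)]
    )


def export_reference_fasta(reps: Sequence[Repertoire], path) -> int:
    """Write all clonotype variable regions as a reference FASTA.

    Header fields (|-separated): clonotype_key, sample_id, chain, method,
    cdr3 span start-end, isotype, size. Sequences wrapped at 80 columns.
    Returns the number of records written.
    """
    missing = [
        ct.clonotype_key for rep in reps for ct in rep.clonotypes if not ct.vdj_aa
    ]
    if missing:
        raise ValueError(f"clonotypes lacking vdj_aa: {missing}")
    n = 0
    handle = open(path, "w") if not hasattr(path, "write") else path
    try:
        for rep in reps:
            for ct in rep.clonotypes:
                handle.write(f">{_fasta_header(ct, rep)}\n")
                seq = ct.vdj_aa
                for i in range(0, len(seq), 80):
                    handle.write(seq[i : i + 80] + "\n")
                n += 1
    finally:
        if handle is not path:
            handle.close()
    return n


def read_reference_fasta(path) -> list[dict]:
    """Parse a reference FASTA back into records matching export metadata."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(path, "fasta"):
        parts = rec.description.split("|")
        if len(parts) != 7:
            raise ValueError(f"unparseable reference header: {rec.description!r}")
        key, sample_id, chain, method, span, isotype, size = parts
        s, e = span.split("-")
        out.append(
            {
                "clonotype_key": key,
                "sample_id": sample_id,
                "chain": chain,
                "method": method,
                "cdr3_span": (int(s), int(e)),
                "isotype": isotype,
                "size": int(size),
                "vdj_aa": str(rec.seq),
            }
        )
    return out
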