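"""Peptide-to-clonotype mapping against personalised BCR references.

Serum antibody digest peptides are matched as exact contiguous substrings
of reference variable-region sequences, then pushed through a four-stage
filter ladder:

1. **all** — peptides that do not map to contaminant proteins;
2. **antibody-specific** — peptides mapping to at least one BCR reference
   (peptides hitting only decoy sequences never reach this stage);
3. **CDR3-overlapping** — peptides whose best reference hit overlaps the
   reference CDR3 by at least 3 contiguous residues;
4. **uniquely mapped** — CDR3-overlapping peptides whose BCR hits all share
   one clonotype identity; these identify a clonotype and allow V(D)J
   sequence reconstruction, and (via single-cell barcodes) recovery of the
   paired chain.

Clonotype identity for the uniqueness rule is evaluated at the amino-acid
level (chain, V gene, J gene, CDR3 aa): peptide evidence cannot distinguish
nucleotide variants, so nucleotide-distinct clonotypes with the same
amino-acid identity count as one. Hits on both bulk and single-cell
references do not make a peptide multi-mapped; they yield source
attribution "both".
"""

from __future__ import annotations

import bisect
import itertools
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .core import Clonotype, Repertoire, SingleCellRepertoire

__all__ = [
    "PeptideRecord",
    "RefEntry",
    "ReferenceIndex",
    "Hit",
    "PeptideMatch",
    "FilterLadder",
    "IdentifiedClonotype",
    "build_reference_index",
    "match_peptides",
    "cdr3_overlap_length",
    "classify_matches",
    "source_attribution",
    "clonal_rank",
    "reconstruct_vdj",
    "recover_paired_chain",
    "class_switch_table",
    "cdr3_edit_distance_distribution",
    "read_maxquant_peptides",
    "levenshtein",
]

SERUM_FRACTIONS = ("IgA", "IgG", "IgK", "IgM")


@dataclass
class PeptideRecord:
    """One serum-digest peptide with its sample annotations."""

    sequence: str
    protease: str = "trypsin"
    serum_fraction: str = "IgG"
    true_source: str | None = None  # ground-truth label in synthetic runs
    ref_isotype: str | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")


@dataclass(frozen=True)
class RefEntry:
    """One reference database entry: a clonotype variable region plus
    provenance (sequencing source, sample, single-cell barcodes)."""

    clonotype: Clonotype
    source: str  # 'bulk' | 'sc'
    sample_id: str
    barcodes: frozenset = frozenset()

    @property
    def vdj_aa(self) -> str:
        return self.clonotype.vdj_aa

    @property
    def aa_identity(self):
        return self.clonotype.aa_identity


class _SubstringIndex:
    """Exact-substring search over many sequences via one concatenated text.

    Sequences are joined with a sentinel character outside the amino-acid
    alphabet; every occurrence of a query is located with str.find and
    mapped back to (sequence index, local offset) by bisection.
    """

    def __init__(self, seqs: list[str]):
        self._starts: list[int] = []
        pos = 0
        parts = []
        for s in seqs:
            self._starts.append(pos)
            parts.append(s)
            pos += len(s) + 1
        self._text = "#".join(parts)
        self._lengths = [len(s) for s in seqs]

    def find_all(self, query: str) -> list[tuple[int, int]]:
        out = []
        pos = self._text.find(query)
        while pos >= 0:
            i = bisect.bisect_right(self._starts, pos) - 1
            local = pos - self._starts[i]
            if local + len(query) <= self._lengths[i]:
                out.append((i, local))
            pos = self._text.find(query, pos + 1)
        return out

    def contains(self, query: str) -> bool:
        return self._text.find(query) >= 0


def _il_fold(s: str) -> str:
    return s.replace("L", "I")


class ReferenceIndex:
    """Search structure over BCR reference entries, decoys and contaminants."""

    def __init__(
        self,
        entries: list[RefEntry],
        decoys: list[str] | None = None,
        contaminants: list[tuple[str, str]] | None = None,
    ):
        if not entries:
            raise ValueError("reference index requires at least one entry")
        for e in entries:
            s, t = e.clonotype.cdr3_span
            if not (0 <= s <= t <= len(e.vdj_aa)):
                raise ValueError(f"invalid cdr3_span for {e.clonotype.clonotype_key}")
        self.entries = entries
        true_seqs = {e.vdj_aa for e in entries}
        # decoys identical to a true reference are rejected at build time
        self.decoys = [d for d in (decoys or []) if d not in true_seqs]
        self.contaminants = list(contaminants or [])
        self._idx = _SubstringIndex([e.vdj_aa for e in entries])
        self._decoy_idx = _SubstringIndex(self.decoys)
        self._cont_idx = _SubstringIndex([s for _, s in self.contaminants])
        self._idx_il = None
        self._decoy_idx_il = None
        self._cont_idx_il = None

    def _il_indexes(self):
        if self._idx_il is None:
            self._idx_il = _SubstringIndex([_il_fold(e.vdj_aa) for e in self.entries])
            self._decoy_idx_il = _SubstringIndex([_il_fold(d) for d in self.decoys])
            self._cont_idx_il = _SubstringIndex(
                [_il_fold(s) for _, s in self.contaminants]
            )
        return self._idx_il, self._decoy_idx_il, self._cont_idx_il

    def search(self, peptide: str, il_equivalence: bool = False):
        """All (entry index, offset) occurrences plus decoy/contaminant flags."""
        if il_equivalence:
            idx, didx, cidx = self._il_indexes()
            q = _il_fold(peptide)
        else:
            idx, didx, cidx = self._idx, self._decoy_idx, self._cont_idx
            q = peptide
        return idx.find_all(q), didx.contains(q), cidx.contains(q)


def build_reference_index(
    bulk_reps: list[Repertoire] = (),
    sc_reps: list[SingleCellRepertoire] = (),
    decoys: list[str] | None = None,
    contaminants: list[tuple[str, str]] | None = None,
) -> ReferenceIndex:
    """Assemble the reference index from bulk and single-cell repertoires.

    Entries are deduplicated at (vdj_aa, clonotype_key) level per source;
    an identical variable region present in both sources is retained once
    per source, which is what later yields the "both" source attribution.
    """
    entries: list[RefEntry] = []
    seen: set[tuple[str, str, str]] = set()
    for source, reps in (("bulk", bulk_reps), ("sc", sc_reps)):
        for rep in reps:
            barcode_map = rep.barcodes if isinstance(rep, SingleCellRepertoire) else {}
            for ct in rep.clonotypes:
                dedup = (ct.vdj_aa, ct.clonotype_key, source)
                if dedup in seen:
                    continue
                seen.add(dedup)
                entries.append(
                    RefEntry(
                        clonotype=ct,
                        source=source,
                        sample_id=rep.sample_id,
                        barcodes=frozenset(barcode_map.get(ct.clonotype_key, ())),
                    )
                )
    return ReferenceIndex(entries, decoys=decoys, contaminants=contaminants)


def cdr3_overlap_length(
    match_span: tuple[int, int], cdr3_span: tuple[int, int]
) -> int:
    """Length of the (contiguous) intersection of two half-open intervals."""
    return max(0, min(match_span[1], cdr3_span[1]) - max(match_span[0], cdr3_span[0]))


@dataclass(frozen=True)
class Hit:
    entry_index: int
    span: tuple[int, int]
    cdr3_overlap_len: int


@dataclass
class PeptideMatch:
    peptide: PeptideRecord
    hits: list[Hit] = field(default_factory=list)
    contaminant_hit: bool = False
    decoy_hit: bool = False
    category: str = "none"  # none|contaminant|all|antibody_specific|cdr3_overlapping
    uniquely_mapped: bool = False

    @property
    def decoy_only_hit(self) -> bool:
        return self.decoy_hit and not self.hits


def match_peptides(
    peptides, index: ReferenceIndex, il_equivalence: bool = False
) -> list[PeptideMatch]:
    """Exact-substring matching of peptides against the reference index.

    Every occurrence within every reference entry is recorded with its
    span and CDR3-overlap length. With ``il_equivalence`` isoleucine and
    leucine form one letter class (mass spectra cannot distinguish them).
    """
    records = _as_peptide_records(peptides)
    out = []
    for rec in records:
        occ, decoy, cont = index.search(rec.sequence, il_equivalence)
        hits = []
        for entry_i, start in occ:
            span = (start, start + len(rec.sequence))
            overlap = cdr3_overlap_length(span, index.entries[entry_i].clonotype.cdr3_span)
            hits.append(Hit(entry_i, span, overlap))
        out.append(
            PeptideMatch(peptide=rec, hits=hits, contaminant_hit=cont, decoy_hit=decoy)
        )
    return out


def _as_peptide_records(peptides) -> list[PeptideRecord]:
    if isinstance(peptides, pd.DataFrame):
        return [
            PeptideRecord(
                sequence=row["sequence"],
                protease=row.get("protease", "trypsin"),
                serum_fraction=row.get("serum_fraction", "IgG"),
                true_source=row.get("true_source"),
                ref_isotype=row.get("ref_isotype"),
            )
            for _, row in peptides.iterrows()
        ]
    return [
        p if isinstance(p, PeptideRecord) else PeptideRecord(sequence=p)
        for p in peptides
    ]


@dataclass
class FilterLadder:
    """Peptide counts surviving each filter stage."""

    all: int
    antibody_specific: int
    cdr3_overlapping: int
    uniquely_mapped: int
    multi_mapped: int

    def __post_init__(self):
        ok = (
            self.all >= self.antibody_specific >= self.cdr3_overlapping
            and self.cdr3_overlapping == self.uniquely_mapped + self.multi_mapped
        )
        if not ok:
            raise ValueError(f"inconsistent filter ladder: {self}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": [
                    "all", "antibody_specific", "cdr3_overlapping",
                    "uniquely_mapped", "multi_mapped",
                ],
                "count": [
                    self.all, self.antibody_specific, self.cdr3_overlapping,
                    self.uniquely_mapped, self.multi_mapped,
                ],
            }
        )


def classify_matches(
    matches: list[PeptideMatch],
    index: ReferenceIndex,
    min_cdr3_overlap: int = 3,
) -> tuple[list[PeptideMatch], FilterLadder]:
    """Apply the four-stage filter ladder in place and count survivors.

    Contaminant-hitting peptides are excluded before the "all" count;
    decoy-only hitters never reach antibody-specific (they have no BCR hit);
    CDR3 overlap is evaluated as the maximum over hits; uniqueness requires
    all BCR hits to share one amino-acid clonotype identity.
    """
    n_all = n_ab = n_cdr3 = n_unique = n_multi = 0
    for m in matches:
        if m.contaminant_hit:
            m.category = "contaminant"
            continue
        n_all += 1
        m.category = "all"
        if not m.hits:
            continue
        n_ab += 1
        m.category = "antibody_specific"
        if max(h.cdr3_overlap_len for h in m.hits) < min_cdr3_overlap:
            continue
        n_cdr3 += 1
        m.category = "cdr3_overlapping"
        identities = {index.entries[h.entry_index].aa_identity for h in m.hits}
        if len(identities) == 1:
            m.uniquely_mapped = True
            n_unique += 1
        else:
            n_multi += 1
    return matches, FilterLadder(n_all, n_ab, n_cdr3, n_unique, n_multi)


def source_attribution(match: PeptideMatch, index: ReferenceIndex) -> str:
    """'bulk', 'sc', or 'both' by the sequencing source of the hits."""
    sources = {index.entries[h.entry_index].source for h in match.hits}
    if not sources:
        return "none"
    if sources == {"bulk", "sc"}:
        return "both"
    return sources.pop()


def clonal_rank(clonotype_key: str, reference: Repertoire) -> int:
    """Competition rank of a clonotype by descending clonal size.

    Ties share the minimum rank; rank 1 is the most expanded clonotype.
    """
    size = None
    for ct in reference.clonotypes:
        if ct.clonotype_key == clonotype_key:
            size = ct.size
            break
    if size is None:
        raise KeyError(f"clonotype {clonotype_key} not in reference {reference.sample_id}")
    return 1 + sum(1 for ct in reference.clonotypes if ct.size > size)


@dataclass
class IdentifiedClonotype:
    """A clonotype identified from uniquely mapped peptides, with the
    recovered V(D)J sequence and (for single-cell sources) the paired chain."""

    clonotype_key: str
    chain: str
    v_gene: str
    j_gene: str
    cdr3_aa: str
    vdj_aa: str
    isotype: str
    source: str
    peptide_sequences: list[str] = field(default_factory=list)
    annotation_spans: list[tuple[int, int]] = field(default_factory=list)
    clonal_rank: int | None = None
    partner_v_gene: str | None = None
    partner_j_gene: str | None = None
    partner_cdr3_aa: str | None = None
    partner_vdj_aa: str | None = None
    partner_ambiguity: float | None = None
    partner_ambiguous: bool = False


def reconstruct_vdj(
    match: PeptideMatch,
    index: ReferenceIndex,
    rank_reference: Repertoire | None = None,
) -> IdentifiedClonotype:
    """Recover the clonal sequence information behind a uniquely mapped peptide.

    Emits the V gene, J gene, CDR3 and full variable-region sequence of the
    matched clonotype, with the peptide's matched segment recorded for
    display. Raises on non-uniquely-mapped matches.
    """
    if not match.uniquely_mapped:
        raise ValueError("reconstruct_vdj requires a uniquely mapped peptide")
    entries = [index.entries[h.entry_index] for h in match.hits]
    # prefer a single-cell entry: it carries barcodes for paired-chain recovery
    rep_entry = next((e for e in entries if e.source == "sc"), entries[0])
    ct = rep_entry.clonotype
    rank = None
    if rank_reference is not None:
        try:
            rank = clonal_rank(ct.clonotype_key, rank_reference)
        except KeyError:
            rank = None
    return IdentifiedClonotype(
        clonotype_key=ct.clonotype_key,
        chain=ct.chain,
        v_gene=ct.v_gene,
        j_gene=ct.j_gene,
        cdr3_aa=ct.cdr3_aa,
        vdj_aa=ct.vdj_aa,
        isotype=ct.isotype,
        source=source_attribution(match, index),
        peptide_sequences=[match.peptide.sequence],
        annotation_spans=[h.span for h in match.hits
                          if index.entries[h.entry_index] is rep_entry],
        clonal_rank=rank,
    )


def recover_paired_chain(
    identified: IdentifiedClonotype, sc_rep: SingleCellRepertoire
) -> IdentifiedClonotype:
    """Fill in the partner chain via the cell barcodes of the identification.

    All cells carrying the identified clonotype (at amino-acid identity)
    vote with their partner-chain clonotype; the majority partner is
    reported with an ambiguity fraction (1 - majority share). A tie is
    flagged ambiguous and broken deterministically by key.
    """
    identity = (identified.chain, identified.v_gene, identified.j_gene, identified.cdr3_aa)
    want_heavy_partner = identified.chain != "heavy"
    votes: dict[str, tuple[int, Clonotype]] = {}
    n_votes = 0
    for cell in sc_rep.cells:
        own = cell.light if want_heavy_partner else cell.heavy
        partner = cell.heavy if want_heavy_partner else cell.light
        if own.aa_identity != identity:
            continue
        n_votes += 1
        key = partner.clonotype_key
        count, _ = votes.get(key, (0, partner))
        votes[key] = (count + 1, partner)
    if n_votes == 0:
        raise ValueError(
            f"no cell barcodes found for identified clonotype {identified.clonotype_key}"
        )
    best_key = min(votes, key=lambda k: (-votes[k][0], k))
    best_count, best_ct = votes[best_key]
    top = sorted((c for c, _ in votes.values()), reverse=True)
    identified.partner_v_gene = best_ct.v_gene
    identified.partner_j_gene = best_ct.j_gene
    identified.partner_cdr3_aa = best_ct.cdr3_aa
    identified.partner_vdj_aa = best_ct.vdj_aa
    identified.partner_ambiguity = 1.0 - best_count / n_votes
    identified.partner_ambiguous = len(top) > 1 and top[0] == top[1]
    return identified


def class_switch_table(
    matches: list[PeptideMatch], index: ReferenceIndex
) -> pd.DataFrame:
    """Cross-tabulate uniquely mapped peptides: reference clonotype isotype
    (rows) against the serum fraction of the supporting peptide (columns)."""
    isotypes = ["IgA", "IgD", "IgG", "IgM", "none"]
    table = pd.DataFrame(0, index=isotypes, columns=list(SERUM_FRACTIONS))
    for m in matches:
        if not m.uniquely_mapped:
            continue
        entry = index.entries[m.hits[0].entry_index]
        iso = entry.clonotype.isotype
        frac = m.peptide.serum_fraction
        if iso in table.index and frac in table.columns:
            table.loc[iso, frac] += 1
    return table


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance."""
    if a == b:
        return 0
    return edlib.align(a, b, task="distance")["editDistance"]


def cdr3_edit_distance_distribution(
    identified: list[IdentifiedClonotype],
) -> np.ndarray:
    """Pairwise Levenshtein distances between identified clonotypes' CDR3s."""
    cdr3s = [ic.cdr3_aa for ic in identified]
    if len(cdr3s) < 2:
        return np.array([], dtype=int)
    return np.array(
        [levenshtein(a, b) for a, b in itertools.combinations(cdr3s, 2)], dtype=int
    )


def read_maxquant_peptides(path) -> list[PeptideRecord]:
    """Read a MaxQuant peptides.txt-like TSV into peptide records.

    Only the Sequence column is required; Proteins, Experiment, protease and
    serum-fraction columns are used when present, extra columns are ignored.
    CON__/REV__ prefixes in Proteins are tolerated (contaminant and decoy
    status is re-derived by matching, not trusted from the table).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower().replace(" ", "_"): c for c in df.columns}
    if "sequence" not in cols:
        raise ValueError("peptide table lacks a Sequence column")
    out = []
    for _, row in df.iterrows():
        protease = row.get(cols.get("protease", ""), None)
        fraction = row.get(cols.get("serum_fraction", cols.get("experiment", "")), None)
        out.append(
            PeptideRecord(
                sequence=row[cols["sequence"]],
                protease=protease if isinstance(protease, str) else "trypsin",
                serum_fraction=fraction if isinstance(fraction, str) else "IgG",
            )
        )
    return out
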