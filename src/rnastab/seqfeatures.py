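"""Sequence-derived stability features.

Everything screened against transcript half-lives is computed here: length,
GC content, k-mer compositions in overlapping (K1) and non-overlapping,
codon-style (K2) modes, degenerate IUPAC motif counts (RNA-binding protein
motifs, the m6A RRACH motif), total protein-binding ability, miRNA target
site counts (parsed from miRanda-format output or a labelled seed-match
stand-in), and 5'/3' fragment series for local secondary-structure analysis.

Coordinates are 0-based half-open throughout; CDS offsets are
transcript-relative. The RNA alphabet is used internally and T is
normalised to U on input.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TranscriptRecord",
    "MotifEntry",
    "IUPAC",
    "normalize_rna",
    "gc_content",
    "kmer_counts_K1",
    "kmer_counts_K2",
    "kmer_frequencies_K1",
    "count_motif_iupac",
    "binding_ability",
    "end_fragments",
    "flanking_fragments",
    "seed_match_interactions",
    "parse_miranda_output",
    "mirna_site_counts",
    "assemble_feature_matrix",
    "all_kmers",
    "read_fasta_records",
    "read_motif_table",
]

#: IUPAC degenerate nucleotide codes over the RNA alphabet
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"), "Y": frozenset("CU"), "S": frozenset("CG"),
    "W": frozenset("AU"), "K": frozenset("GU"), "M": frozenset("AC"),
    "B": frozenset("CGU"), "D": frozenset("AGU"), "H": frozenset("ACU"),
    "V": frozenset("ACG"), "N": frozenset("ACGU"),
}

_BASES = "ACGU"
_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def normalize_rna(sequence: str) -> str:
    """Uppercase and spell in the RNA alphabet (T -> U)."""
    return sequence.upper().replace("T", "U")


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript: sequence, biotype and annotation needed downstream."""

    transcript_id: str
    sequence: str
    biotype: str = "lncRNA"
    exon_count: int = 1
    lnc_class: str = "none"
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if self.biotype not in ("lncRNA", "mRNA"):
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if self.exon_count < 1:
            raise ValueError("exon_count must be >= 1")
        if self.biotype == "mRNA":
            if self.cds_start is None or self.cds_end is None:
                raise ValueError("mRNA requires CDS offsets")
            if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
                raise ValueError("CDS offsets out of range")
            if (self.cds_end - self.cds_start) % 3:
                raise ValueError("CDS length must be a multiple of 3")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def cds(self) -> str:
        if self.cds_start is None:
            raise ValueError("not an mRNA record")
        return self.sequence[self.cds_start:self.cds_end]

    @property
    def utr5(self) -> str:
        if self.cds_start is None:
            raise ValueError("not an mRNA record")
        return self.sequence[:self.cds_start]

    @property
    def utr3(self) -> str:
        if self.cds_end is None:
            raise ValueError("not an mRNA record")
        return self.sequence[self.cds_end:]


@dataclass(frozen=True)
class MotifEntry:
    """IUPAC motif with the protein (or label) it is recognised by."""

    motif: str
    source_id: str = ""

    def __post_init__(self) -> None:
        m = normalize_rna(self.motif)
        if not m:
            raise ValueError("empty motif")
        bad = set(m) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC characters: {sorted(bad)}")
        object.__setattr__(self, "motif", m)


def gc_content(sequence: str) -> float:
    """(G + C) / number of unambiguous bases."""
    seq = normalize_rna(sequence)
    if not seq:
        raise ValueError("empty sequence")
    n_acgu = sum(seq.count(b) for b in _BASES)
    if n_acgu == 0:
        raise ValueError("no unambiguous bases")
    return (seq.count("G") + seq.count("C")) / n_acgu


def _check_k(k: int) -> None:
    if not 1 <= k <= 6:
        raise ValueError("k must be in 1..6")


def kmer_counts_K1(sequence: str, k: int) -> dict[str, int]:
    """Overlapping k-mer counts: sliding window, step 1.

    Windows containing an ambiguous base are skipped, so for an unambiguous
    sequence of length L >= k the counts sum to L - k + 1.
    """
    _check_k(k)
    seq = normalize_rna(sequence)
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i:i + k]
        if all(b in _BASES for b in w):
            counts[w] = counts.get(w, 0) + 1
    return counts


def kmer_counts_K2(sequence: str, k: int, frame_offset: int = 0) -> dict[str, int]:
    """Non-overlapping, codon-style k-mer counts starting at ``frame_offset``.

    The trailing partial window is dropped; with k=3 and
    ``frame_offset=cds_start`` this is exactly codon content.
    """
    _check_k(k)
    if frame_offset < 0:
        raise ValueError("frame_offset must be >= 0")
    seq = normalize_rna(sequence)
    counts: dict[str, int] = {}
    for i in range(frame_offset, len(seq) - k + 1, k):
        w = seq[i:i + k]
        if all(b in _BASES for b in w):
            counts[w] = counts.get(w, 0) + 1
    return counts


def all_kmers(k: int) -> list[str]:
    """All 4**k k-mers over ACGU in lexicographic order."""
    return ["".join(p) for p in itertools.product(_BASES, repeat=k)]


def kmer_frequencies_K1(sequence: str, ks=(1, 2, 3, 4, 5, 6)) -> dict[str, float]:
    """Length-normalised K1 frequencies for every k in ``ks``.

    Frequencies within one k sum to 1 (0 vector when the sequence is
    shorter than k); keys cover the full 4**k space.
    """
    out: dict[str, float] = {}
    seq = normalize_rna(sequence)
    for k in ks:
        counts = kmer_counts_K1(seq, k)
        total = sum(counts.values())
        for km in all_kmers(k):
            out[km] = counts.get(km, 0) / total if total else 0.0
    return out


def _motif_regex(motif: str) -> re.Pattern:
    body = "".join(
        b if len(IUPAC[b]) == 1 else "[" + "".join(sorted(IUPAC[b])) + "]"
        for b in motif)
    return re.compile(f"(?=({body}))")  # lookahead: overlapping occurrences


def count_motif_iupac(sequence: str, motif: str) -> int:
    """Occurrences of a degenerate IUPAC motif, overlapping allowed."""
    entry = MotifEntry(motif)
    seq = normalize_rna(sequence)
    return sum(1 for _ in _motif_regex(entry.motif).finditer(seq))


def binding_ability(sequence: str, motifs) -> tuple[int, dict[str, int], dict[str, int]]:
    """Total, per-motif and per-source motif occurrence counts.

    The total over all motifs is the transcript's protein-binding ability.
    """
    motifs = list(motifs)
    if not motifs:
        raise ValueError("need at least one motif")
    per_motif: dict[str, int] = {}
    per_source: dict[str, int] = {}
    for entry in motifs:
        if not isinstance(entry, MotifEntry):
            entry = MotifEntry(*entry) if isinstance(entry, tuple) else MotifEntry(entry)
        c = count_motif_iupac(sequence, entry.motif)
        per_motif[entry.motif] = per_motif.get(entry.motif, 0) + c
        per_source[entry.source_id] = per_source.get(entry.source_id, 0) + c
    return sum(per_motif.values()), per_motif, per_source


DEFAULT_FRAGMENT_LENGTHS = tuple(range(50, 301, 10))       # 26 lengths
DEFAULT_FLANK_LENGTHS = tuple(range(100, 601, 20))         # 26 total widths


def end_fragments(sequence: str, end: str,
                  lengths=DEFAULT_FRAGMENT_LENGTHS) -> list[tuple[int, str]]:
    """Prefix (five_prime) or suffix (three_prime) fragments of each length.

    Lengths exceeding the sequence are skipped so every returned fragment of
    a given nominal length is directly comparable across transcripts.
    """
    seq = normalize_rna(sequence)
    if not seq:
        raise ValueError("empty sequence")
    if end not in ("five_prime", "three_prime"):
        raise ValueError("end must be 'five_prime' or 'three_prime'")
    out = []
    for L in lengths:
        if L > len(seq):
            continue
        out.append((L, seq[:L] if end == "five_prime" else seq[-L:]))
    return out


def flanking_fragments(record: TranscriptRecord,
                       total_lengths=DEFAULT_FLANK_LENGTHS,
                       ) -> dict[str, list[tuple[int, str]]]:
    """Windows centred on the start and stop codon boundaries of an mRNA.

    For total width L the 5' window is sequence[cds_start - L/2,
    cds_start + L/2) and the 3' window is centred on cds_end; windows that
    would overrun the transcript are skipped, not clipped.
    """
    if record.biotype != "mRNA":
        raise ValueError("flanking fragments are defined for mRNA records")
    seq = record.sequence
    out: dict[str, list[tuple[int, str]]] = {"five_prime": [], "three_prime": []}
    for L in total_lengths:
        half = L // 2
        for key, centre in (("five_prime", record.cds_start),
                            ("three_prime", record.cds_end)):
            lo, hi = centre - half, centre + half
            if lo < 0 or hi > len(seq):
                continue
            out[key].append((L, seq[lo:hi]))
    return out


# ---------------------------------------------------------------------------
# miRNA target sites


def seed_match_interactions(records, mirnas: dict[str, str]
                            ) -> list[tuple[str, str, int]]:
    """Seed-match stand-in for a target predictor (synthetic interactions).

    For each miRNA the seed (bases 2-8) is reverse-complemented and every
    exact, possibly overlapping occurrence in the target is one interaction:
    (mirna_id, transcript_id, start position). This is a labelled stand-in,
    not a thermodynamic target predictor.
    """
    hits = []
    for mid, mseq in mirnas.items():
        seed = normalize_rna(mseq)[1:8]
        if len(seed) < 7:
            raise ValueError(f"miRNA {mid} shorter than 8 nt")
        site = seed.translate(_COMPLEMENT)[::-1]
        pat = re.compile(f"(?=({re.escape(site)}))")
        for rec in records:
            for m in pat.finditer(rec.sequence):
                hits.append((mid, rec.transcript_id, m.start()))
    return hits


def parse_miranda_output(text: str) -> list[tuple[str, str, int]]:
    """Parse miRanda-format output into (mirna, target, start) hits.

    Individual hit lines start with a single ``>`` (summary lines start with
    ``>>``) and carry whitespace-separated fields: query id, target id,
    score, energy, query range, target range (start end). Malformed hit
    lines raise with their line number.
    """
    hits = []
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line.startswith(">") or line.startswith(">>"):
            continue
        fields = line[1:].split()
        if len(fields) < 8:
            raise ValueError(f"malformed miRanda hit at line {ln}: {line!r}")
        try:
            start = int(fields[6])
        except ValueError as exc:
            raise ValueError(f"malformed miRanda hit at line {ln}") from exc
        hits.append((fields[0], fields[1], start))
    return hits


def mirna_site_counts(records, interactions) -> tuple[pd.DataFrame, pd.Series]:
    """Per-(miRNA, transcript) site counts and per-transcript totals.

    When CDS offsets exist the hit start position attributes the site to the
    5'UTR, CDS or 3'UTR region.
    """
    recs = {r.transcript_id: r for r in records}
    rows: dict[tuple[str, str], dict[str, int]] = {}
    for mid, tid, start in interactions:
        key = (mid, tid)
        row = rows.setdefault(key, {"count": 0, "utr5": 0, "cds": 0, "utr3": 0})
        row["count"] += 1
        rec = recs.get(tid)
        if rec is not None and rec.cds_start is not None:
            if start < rec.cds_start:
                row["utr5"] += 1
            elif start < rec.cds_end:
                row["cds"] += 1
            else:
                row["utr3"] += 1
    pair = pd.DataFrame(
        [{"mirna_id": m, "transcript_id": t, **vals}
         for (m, t), vals in sorted(rows.items())],
        columns=["mirna_id", "transcript_id", "count", "utr5", "cds", "utr3"])
    totals = (pair.groupby("transcript_id")["count"].sum()
              if len(pair) else pd.Series(dtype=int))
    totals = totals.reindex(sorted(recs), fill_value=0)
    totals.name = "mirna_sites_total"
    return pair, totals


# ---------------------------------------------------------------------------
# feature matrix assembly


def assemble_feature_matrix(records, motifs=(), mirnas=(),
                            structure_energies: dict[str, float] | None = None,
                            ks=(1, 2, 3, 4, 5, 6)) -> pd.DataFrame:
    """Transcript x feature matrix for stability screening.

    Columns: K1 k-mer frequencies for every k in ``ks`` (5460 for k=1..6),
    one count column per motif plus ``binding_total``, one count column per
    miRNA plus ``mirna_sites_total``, and the basic properties ``mfe``
    (secondary-structure free energy, NaN when not supplied), ``length``
    and ``gc``. With the full motif (2297) and miRNA (2656) complements
    this is 10,418 columns.
    """
    records = list(records)
    ids = [r.transcript_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate transcript ids")
    motifs = [m if isinstance(m, MotifEntry) else MotifEntry(m) for m in motifs]
    mirnas = dict(mirnas)
    if structure_energies:
        unknown = sorted(set(structure_energies) - set(ids))
        if unknown:
            raise ValueError(f"structure energies for unknown ids: {unknown}")

    kmer_cols = [km for k in ks for km in all_kmers(k)]
    rows = []
    for rec in records:
        row: dict[str, float] = {}
        row.update(kmer_frequencies_K1(rec.sequence, ks))
        if motifs:
            total, per_motif, _ = binding_ability(rec.sequence, motifs)
            for entry in motifs:
                row[f"motif_{entry.motif}"] = per_motif[entry.motif]
            row["binding_total"] = total
        rows.append(row)

    index = pd.Index(ids, name="transcript_id")
    blocks = [pd.DataFrame(rows, index=index)]
    if mirnas:
        hits = seed_match_interactions(records, mirnas)
        pair, totals = mirna_site_counts(records, hits)
        counts = pair.pivot_table(index="transcript_id", columns="mirna_id",
                                  values="count", fill_value=0)
        mir_block = {f"mirna_{mid}":
                     (counts[mid].reindex(index).fillna(0)
                      if mid in counts.columns else pd.Series(0.0, index=index))
                     for mid in sorted(mirnas)}
        mir_block["mirna_sites_total"] = totals.reindex(index).fillna(0)
        blocks.append(pd.DataFrame(mir_block, index=index))
    blocks.append(pd.DataFrame({
        "mfe": pd.Series(structure_energies or {}, dtype=float).reindex(index),
        "length": [float(r.length) for r in records],
        "gc": [gc_content(r.sequence) for r in records],
    }, index=index))
    mat = pd.concat(blocks, axis=1)

    ordered = (kmer_cols
               + [f"motif_{m.motif}" for m in motifs]
               + (["binding_total"] if motifs else [])
               + [f"mirna_{m}" for m in sorted(mirnas)]
               + (["mirna_sites_total"] if mirnas else [])
               + ["mfe", "length", "gc"])
    return mat[ordered]


# ---------------------------------------------------------------------------
# readers


def read_fasta_records(path, annotations: pd.DataFrame | None = None
                       ) -> list[TranscriptRecord]:
    """Read transcripts from FASTA, optionally joining an annotation table.

    ``annotations`` (indexed by transcript_id or with that column) may carry
    biotype, exon_count, lnc_class, cds_start and cds_end.
    """
    from Bio import SeqIO

    ann = None
    if annotations is not None:
        ann = annotations
        if "transcript_id" in ann.columns:
            ann = ann.set_index("transcript_id")
    out = []
    for seqrec in SeqIO.parse(str(path), "fasta"):
        kwargs: dict = {}
        if ann is not None and seqrec.id in ann.index:
            row = ann.loc[seqrec.id]
            for key in ("biotype", "lnc_class"):
                if key in row and pd.notna(row[key]):
                    kwargs[key] = str(row[key])
            for key in ("exon_count", "cds_start", "cds_end"):
                if key in row and pd.notna(row[key]):
                    kwargs[key] = int(row[key])
        out.append(TranscriptRecord(seqrec.id, str(seqrec.seq), **kwargs))
    return out


def read_motif_table(path) -> list[MotifEntry]:
    """Read a TSV motif list with columns motif[, source]."""
    table = pd.read_csv(path, sep="\t")
    if "motif" not in table.columns:
        raise ValueError("motif table needs a 'motif' column")
    src = table["source"] if "source" in table.columns else [""] * len(table)
    return [MotifEntry(m, str(s)) for m, s in zip(table["motif"], src)]
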