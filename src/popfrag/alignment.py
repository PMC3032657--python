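"""Gene-fragment alignments: reading, polymorphic-site calling, effect classes.

Sequences are haploid (one gamete per line), stored as equal-length rows
over the alphabet {A, C, G, T, -, N}.  Coordinates are 0-based half-open
internally; report layers add 1-based "SNP1" style numbering.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from popfrag._codon import polarity_differs, translate_codon

logger = logging.getLogger(__name__)

REGION_TYPES = ("5UTR", "exon", "intron", "3UTR")

#: columns of the site table (one row per polymorphic site)
SITE_COLUMNS = [
    "position",        # 0-based alignment column (indel: anchor column)
    "kind",            # "SNP" | "indel"
    "alleles",         # tuple of allele codes, ordered by descending count
    "counts",          # tuple of ints, same order
    "length",          # indel length in columns (SNP: 1)
    "maf",             # frequency of the second most frequent allele
    "region",          # 5UTR/exon/intron/3UTR or None
    "coding_effect",   # synonymous | non-synonymous | frameshift-free-indel
                       # | non-coding | NA
    "polarity_change",  # bool or None
    "flags",           # free-text flags (e.g. frameshift)
]

MAX_N_FRACTION = 0.20  # rows with more missing data than this are dropped


@dataclass(frozen=True)
class GeneAnnotation:
    """Region intervals of a gene fragment plus the reading-frame offset.

    ``intervals`` are (start, end, region) triples, 0-based half-open,
    sorted and disjoint.  ``frame_offset`` is the codon position (0|1|2)
    of the first exonic base.
    """

    intervals: tuple[tuple[int, int, str], ...]
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.frame_offset not in (0, 1, 2):
            raise ValueError(f"frame_offset must be 0|1|2, got {self.frame_offset}")
        prev_end = 0
        for start, end, region in self.intervals:
            if region not in REGION_TYPES:
                raise ValueError(f"unknown region type {region!r}")
            if start < prev_end or end <= start:
                raise ValueError("annotation intervals must be sorted and disjoint")
            prev_end = end

    @property
    def length(self) -> int:
        return self.intervals[-1][1] if self.intervals else 0

    def region_at(self, pos: int) -> str | None:
        for start, end, region in self.intervals:
            if start <= pos < end:
                return region
        return None

    def exon_columns(self) -> np.ndarray:
        """Alignment columns of the coding sequence, in 5'→3' order."""
        cols = [
            np.arange(start, end)
            for start, end, region in self.intervals
            if region == "exon"
        ]
        if not cols:
            return np.empty(0, dtype=int)
        return np.concatenate(cols)

    def region_mask(self, region: str, length: int | None = None) -> np.ndarray:
        """Boolean mask over alignment columns for one region type."""
        length = length if length is not None else self.length
        mask = np.zeros(length, dtype=bool)
        for start, end, reg in self.intervals:
            if reg == region:
                mask[start:end] = True
        return mask


@dataclass
class HaplotypeAlignment:
    """Equal-length haploid sequences of one gene fragment."""

    gene_id: str
    seqs: np.ndarray  # (n_rows, n_cols) of single characters
    line_ids: list[str]
    populations: list[str]
    annotation: GeneAnnotation | None = None

    def __post_init__(self) -> None:
        self.seqs = np.asarray(self.seqs, dtype="U1")
        if self.seqs.ndim != 2:
            raise ValueError("seqs must be a 2-D character array")
        n = self.seqs.shape[0]
        if len(self.line_ids) != n or len(self.populations) != n:
            raise ValueError("line_ids/populations length must match row count")
        if len(set(self.line_ids)) != n:
            raise ValueError("line_ids must be unique")

    @property
    def n_rows(self) -> int:
        return self.seqs.shape[0]

    @property
    def n_cols(self) -> int:
        return self.seqs.shape[1]

    def row(self, i: int) -> str:
        return "".join(self.seqs[i])

    def subset_rows(self, idx: np.ndarray) -> "HaplotypeAlignment":
        return HaplotypeAlignment(
            gene_id=self.gene_id,
            seqs=self.seqs[idx],
            line_ids=[self.line_ids[i] for i in np.atleast_1d(idx)],
            populations=[self.populations[i] for i in np.atleast_1d(idx)],
            annotation=self.annotation,
        )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_populations(path) -> dict[str, str]:
    """Read a two-column line_id,population CSV into a mapping."""
    table: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if [h.strip().lower() for h in header[:2]] != ["line_id", "population"]:
            raise ValueError(f"{path}: expected header line_id,population")
        for row in reader:
            if row:
                table[row[0]] = row[1]
    return table


def read_annotation(path) -> GeneAnnotation:
    """Read a BED-like annotation: start, end, region_type, frame (tab-sep)."""
    intervals: list[tuple[int, int, str]] = []
    frame_offset = 0
    frame_seen = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            start, end, region = int(fields[0]), int(fields[1]), fields[2]
            intervals.append((start, end, region))
            if region == "exon" and not frame_seen and len(fields) > 3 and fields[3] != ".":
                frame_offset = int(fields[3])
                frame_seen = True
    return GeneAnnotation(tuple(intervals), frame_offset)


def write_annotation(annotation: GeneAnnotation, path) -> None:
    first_exon = True
    with open(path, "w") as fh:
        for start, end, region in annotation.intervals:
            frame = "."
            if region == "exon" and first_exon:
                frame = str(annotation.frame_offset)
                first_exon = False
            fh.write(f"{start}\t{end}\t{region}\t{frame}\n")


def read_alignment(fasta_path, annotation_path, populations_path,
                   gene_id: str | None = None) -> HaplotypeAlignment:
    """Read one gene alignment; rows with >20% N are dropped with a warning."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"{fasta_path}: no FASTA records")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        bad = [r.id for r in records if len(r.seq) != len(records[0].seq)]
        raise ValueError(f"{fasta_path}: ragged alignment, offending records: {bad}")
    pops = read_populations(populations_path)
    line_ids, populations, rows = [], [], []
    for rec in records:
        seq = str(rec.seq).upper()
        if rec.id not in pops:
            raise ValueError(
                f"{fasta_path}: record {rec.id!r} absent from population table")
        n_frac = seq.count("N") / len(seq)
        if n_frac > MAX_N_FRACTION:
            logger.warning("dropping %s (%.0f%% N)", rec.id, 100 * n_frac)
            continue
        line_ids.append(rec.id)
        populations.append(pops[rec.id])
        rows.append(list(seq))
    annotation = read_annotation(annotation_path) if annotation_path else None
    if gene_id is None:
        import os
        gene_id = os.path.splitext(os.path.basename(str(fasta_path)))[0]
    return HaplotypeAlignment(gene_id, np.array(rows, dtype="U1"),
                              line_ids, populations, annotation)


def write_alignment(aln: HaplotypeAlignment, path) -> None:
    with open(path, "w") as fh:
        for i, line_id in enumerate(aln.line_ids):
            fh.write(f">{line_id} pop={aln.populations[i]}\n{aln.row(i)}\n")


# ---------------------------------------------------------------------------
# polymorphic-site calling
# ---------------------------------------------------------------------------

def _gap_runs(row: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of '-' in one sequence row, as (start, end) half-open."""
    isgap = row == "-"
    if not isgap.any():
        return []
    diff = np.diff(isgap.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1) + 1)
    if isgap[0]:
        starts.insert(0, 0)
    if isgap[-1]:
        ends.append(len(row))
    return list(zip(starts, ends))


def call_sites(aln: HaplotypeAlignment) -> pd.DataFrame:
    """Scan the alignment for SNPs and indels.

    A column with at least two non-missing residues and at least two
    distinct residues (gaps excluded) is a SNP.  A maximal gap run with
    identical start/end across its carriers is one indel site anchored at
    its first column; carriers with a different extent form separate
    indel sites.
    """
    if aln.n_rows < 2:
        raise ValueError("need at least 2 rows to call sites")
    seqs = aln.seqs
    ann = aln.annotation
    records: list[dict] = []

    # --- indels: group identical gap runs
    run_carriers: dict[tuple[int, int], list[int]] = {}
    for i in range(aln.n_rows):
        for run in _gap_runs(seqs[i]):
            run_carriers.setdefault(run, []).append(i)
    for (start, end), carriers in sorted(run_carriers.items()):
        n_carrier = len(carriers)
        n_absent = 0
        for i in range(aln.n_rows):
            if i in carriers:
                continue
            window = seqs[i, start:end]
            if "-" not in window and "N" not in window:
                n_absent += 1
        total = n_carrier + n_absent
        if n_absent == 0 or n_carrier == 0:
            continue  # not polymorphic among scorable rows
        counts = tuple(sorted((n_absent, n_carrier), reverse=True))
        alleles = ("ref", "del") if n_absent >= n_carrier else ("del", "ref")
        records.append({
            "position": start,
            "kind": "indel",
            "alleles": alleles,
            "counts": counts,
            "length": end - start,
            "maf": counts[1] / total,
            "region": ann.region_at(start) if ann else None,
            "coding_effect": "NA",
            "polarity_change": None,
            "flags": "",
        })

    # --- SNPs: column-wise residue counts, gaps and N excluded
    for j in range(aln.n_cols):
        col = seqs[:, j]
        keep = (col != "N") & (col != "-")
        residues = col[keep]
        if residues.size < 2:
            continue
        alleles, counts = np.unique(residues, return_counts=True)
        if alleles.size < 2:
            continue
        order = np.argsort(-counts, kind="stable")
        alleles, counts = alleles[order], counts[order]
        records.append({
            "position": j,
            "kind": "SNP",
            "alleles": tuple(alleles),
            "counts": tuple(int(c) for c in counts),
            "length": 1,
            "maf": counts[1] / counts.sum(),
            "region": ann.region_at(j) if ann else None,
            "coding_effect": "NA",
            "polarity_change": None,
            "flags": "",
        })

    sites = pd.DataFrame(records, columns=SITE_COLUMNS)
    if len(sites):
        sites = sites.sort_values(
            ["position", "kind"], kind="stable").reset_index(drop=True)
    return sites


# ---------------------------------------------------------------------------
# functional classification
# ---------------------------------------------------------------------------

def _consensus(col: np.ndarray) -> str | None:
    keep = (col != "N") & (col != "-")
    if not keep.any():
        return None
    alleles, counts = np.unique(col[keep], return_counts=True)
    return str(alleles[np.argmax(counts)])


def classify_effects(sites: pd.DataFrame, aln: HaplotypeAlignment) -> pd.DataFrame:
    """Assign coding effects to each polymorphic site.

    Exonic SNPs are translated in the annotated frame against the
    consensus background at the other codon positions.  Exonic indels
    with length divisible by 3 are frameshift-free; other exonic indels
    are flagged but not classified.  Non-exonic sites are non-coding.
    """
    ann = aln.annotation
    if ann is None:
        raise ValueError("classify_effects requires an annotation")
    exon_cols = ann.exon_columns()
    col_to_cds = {int(c): i for i, c in enumerate(exon_cols)}
    n_cds = len(exon_cols)
    out = sites.copy()

    for idx, site in sites.iterrows():
        region = site["region"]
        if region != "exon":
            out.at[idx, "coding_effect"] = "non-coding"
            continue
        if site["kind"] == "indel":
            if site["length"] % 3 == 0:
                out.at[idx, "coding_effect"] = "frameshift-free-indel"
            else:
                out.at[idx, "coding_effect"] = "NA"
                out.at[idx, "flags"] = "frameshift"
            continue
        # exonic SNP: rebuild the codon around the site
        cds_i = col_to_cds[int(site["position"])]
        codon_pos = (cds_i + ann.frame_offset) % 3
        codon_start = cds_i - codon_pos
        if codon_start < 0 or codon_start + 3 > n_cds:
            out.at[idx, "coding_effect"] = "NA"
            out.at[idx, "flags"] = "incomplete-codon"
            continue
        codon = []
        ok = True
        for k in range(3):
            c = _consensus(aln.seqs[:, exon_cols[codon_start + k]])
            if c is None:
                ok = False
                break
            codon.append(c)
        if not ok:
            out.at[idx, "coding_effect"] = "NA"
            out.at[idx, "flags"] = "unresolvable-codon"
            continue
        major, minors = site["alleles"][0], site["alleles"][1:]
        codon[codon_pos] = major
        aa_major = translate_codon("".join(codon))
        synonymous = True
        polarity = False
        polarity_known = True
        for alt in minors:
            codon[codon_pos] = alt
            aa_alt = translate_codon("".join(codon))
            if aa_alt != aa_major:
                synonymous = False
                diff = polarity_differs(aa_major, aa_alt)
                if diff is None:
                    polarity_known = False
                elif diff:
                    polarity = True
        out.at[idx, "coding_effect"] = "synonymous" if synonymous else "non-synonymous"
        if synonymous:
            out.at[idx, "polarity_change"] = None
        else:
            out.at[idx, "polarity_change"] = polarity if polarity_known else None
    return out


def filter_maf(sites: pd.DataFrame, threshold: float = 0.05) -> pd.DataFrame:
    """Keep sites with MAF >= threshold (a site at exactly the threshold stays)."""
    if len(sites) == 0:
        return sites
    return sites[sites["maf"] >= threshold].reset_index(drop=True)


# ---------------------------------------------------------------------------
# per-line genotypes over polymorphic sites
# ---------------------------------------------------------------------------

def site_genotypes(aln: HaplotypeAlignment, sites: pd.DataFrame) -> pd.DataFrame:
    """Per-line allele calls over the polymorphic sites.

    Returns a lines x sites DataFrame of allele codes (residue for SNPs,
    'del'/'ref' for indels); missing data are NaN.  Column labels are
    "<kind>@<position>".
    """
    data: dict[str, list] = {}
    for _, site in sites.iterrows():
        pos = int(site["position"])
        label = f"{site['kind']}@{pos}"
        if site["kind"] == "SNP":
            col = aln.seqs[:, pos]
            vals = [c if c not in ("N", "-") else np.nan for c in col]
        else:
            end = pos + int(site["length"])
            vals = []
            for i in range(aln.n_rows):
                window = aln.seqs[i, pos:end]
                if (window == "-").all():
                    # carrier only when the run matches exactly
                    left_gap = pos > 0 and aln.seqs[i, pos - 1] == "-"
                    right_gap = end < aln.n_cols and aln.seqs[i, end] == "-"
                    vals.append(np.nan if (left_gap or right_gap) else "del")
                elif "-" in window or "N" in window:
                    vals.append(np.nan)
                else:
                    vals.append("ref")
        data[label] = vals
    return pd.DataFrame(data, index=aln.line_ids, dtype=object)


def write_site_table(sites: pd.DataFrame, path) -> None:
    flat = sites.copy()
    flat["alleles"] = flat["alleles"].map(lambda t: "/".join(map(str, t)))
    flat["counts"] = flat["counts"].map(lambda t: "/".join(map(str, t)))
    flat.to_csv(path, index=False)
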