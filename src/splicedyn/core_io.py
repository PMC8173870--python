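"""Shared data model and readers/writers for every table the pipeline touches.

Coordinate convention: all genomic intervals are stored 0-based
half-open. GTF input (1-based inclusive) is converted on read with
``start - 1`` / ``end``. Transcript exons are kept sorted 5'→3' in
transcript orientation, i.e. descending genomic coordinates on the
minus strand.

PSI is kept on the 0–100 scale throughout; z-scaling happens only
inside the clustering module, because every calling threshold
(10, 5, 2) is defined on the PSI scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from splicedyn.config import DEFAULTS

QUAL_OK = "OK"
QUAL_VLOW = "VLOW"
QUAL_NA = "NA"

EVENT_TYPES = ("CEx", "MIC", "Alt5", "Alt3", "IR")

_META_COLS = [
    "event_id", "gene_id", "event_type", "chrom",
    "span_start", "span_end", "exon_start", "exon_end", "strand",
]


# ---------------------------------------------------------------------------
# sample map
# ---------------------------------------------------------------------------

@dataclass
class SampleMap:
    """Sample → condition/replicate/dataset assignment.

    ``table`` is indexed by sample_id with columns ``condition``,
    ``replicate`` (1-based, contiguous within condition) and
    ``dataset``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        for col in ("condition", "replicate", "dataset"):
            if col not in t.columns:
                raise ValueError(f"sample map lacks column {col!r}")
        for cond, grp in t.groupby("condition"):
            reps = sorted(int(r) for r in grp["replicate"])
            if reps != list(range(1, len(reps) + 1)):
                raise ValueError(
                    f"replicates of condition {cond!r} not contiguous from 1: {reps}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.table["condition"]:
            seen.setdefault(c, None)
        return list(seen)

    def samples_of(self, condition: str) -> list[str]:
        hit = self.table.index[self.table["condition"] == condition]
        if len(hit) == 0:
            raise KeyError(f"unknown condition {condition!r}")
        return list(hit)

    def subset(self, sample_ids: Sequence[str]) -> "SampleMap":
        sub = self.table.loc[list(sample_ids)].copy()
        # renumber replicates so the contiguity invariant survives subsetting
        for cond, grp in sub.groupby("condition"):
            order = grp["replicate"].sort_values().index
            sub.loc[order, "replicate"] = range(1, len(order) + 1)
        return SampleMap(sub)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SampleMap) and self.table.equals(other.table)


def read_sample_map(path: str) -> SampleMap:
    t = pd.read_csv(path, sep="\t", dtype={"sample_id": str}).set_index("sample_id")
    return SampleMap(t)


def write_sample_map(m: SampleMap, path: str) -> str:
    m.table.to_csv(path, sep="\t", index_label="sample_id")
    return path


# ---------------------------------------------------------------------------
# splice events and PSI tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpliceEvent:
    """One alternative-splicing event; ``span`` is the largest junction."""

    event_id: str
    gene_id: str
    event_type: str
    chrom: str
    span_start: int
    span_end: int
    exon_start: int
    exon_end: int
    strand: str

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"bad event type {self.event_type!r}")
        if not self.span_start < self.span_end:
            raise ValueError(f"{self.event_id}: span_start >= span_end")
        if not (self.span_start <= self.exon_start < self.exon_end <= self.span_end):
            raise ValueError(f"{self.event_id}: exon not contained in span")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.event_id}: bad strand {self.strand!r}")


def quality_from_reads(reads: pd.DataFrame, psi: pd.DataFrame,
                       min_reads: int = DEFAULTS["min_reads"]) -> pd.DataFrame:
    """Quality flags: NA where PSI is missing, VLOW below the read floor."""
    q = pd.DataFrame(QUAL_OK, index=psi.index, columns=psi.columns)
    q = q.mask(reads < min_reads, QUAL_VLOW)
    q = q.mask(psi.isna(), QUAL_NA)
    return q


@dataclass
class PsiTable:
    """Events × samples PSI matrix with read support and quality flags."""

    events: list[SpliceEvent]
    samples: SampleMap
    psi: pd.DataFrame
    reads: pd.DataFrame
    quality: pd.DataFrame

    def __post_init__(self) -> None:
        ids = [e.event_id for e in self.events]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate event_id in events")
        for name, m in (("psi", self.psi), ("reads", self.reads),
                        ("quality", self.quality)):
            if list(m.index) != ids:
                raise ValueError(f"{name} index does not match events")
            if list(m.columns) != self.samples.sample_ids:
                raise ValueError(f"{name} columns do not match sample map")
        vals = self.psi.to_numpy(float)
        ok = np.isnan(vals) | ((vals >= 0) & (vals <= 100))
        if not ok.all():
            raise ValueError("PSI values outside [0, 100]")
        if (self.reads.to_numpy() < 0).any():
            raise ValueError("negative read support")

    @classmethod
    def build(cls, events: list[SpliceEvent], samples: SampleMap,
              psi: pd.DataFrame, reads: pd.DataFrame,
              min_reads: int = DEFAULTS["min_reads"]) -> "PsiTable":
        """Assemble a table, deriving quality flags from read support."""
        q = quality_from_reads(reads, psi, min_reads)
        return cls(events, samples, psi, reads, q)

    @property
    def event_ids(self) -> list[str]:
        return list(self.psi.index)

    def event(self, event_id: str) -> SpliceEvent:
        for e in self.events:
            if e.event_id == event_id:
                return e
        raise KeyError(event_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PsiTable):
            return NotImplemented
        psi_a = self.psi.round(2)
        psi_b = other.psi.round(2)
        same_psi = ((psi_a.isna() & psi_b.isna()) | (psi_a == psi_b)).all().all()
        return bool(
            self.events == other.events
            and self.samples == other.samples
            and same_psi
            and self.reads.equals(other.reads)
            and self.quality.equals(other.quality)
        )


def write_psi_table(t: PsiTable, path: str) -> str:
    """Serialize a PsiTable as TSV; PSI is written rounded to 2 decimals.

    Layout: event metadata columns, then for each sample a PSI column
    named after the sample and a ``<sample>.reads`` column.
    """
    meta = pd.DataFrame(
        [[getattr(e, c) for c in _META_COLS] for e in t.events],
        columns=_META_COLS,
    )
    out = meta.set_index("event_id")
    for sid in t.samples.sample_ids:
        out[sid] = t.psi[sid].round(2).map(
            lambda v: "" if pd.isna(v) else f"{v:.2f}")
        out[f"{sid}.reads"] = t.reads[sid].astype(int)
    out.to_csv(path, sep="\t", index_label="event_id")
    return path


def read_psi_table(path: str, sample_map: str | SampleMap,
                   min_reads: int = DEFAULTS["min_reads"]) -> PsiTable:
    """Read a PSI TSV written by :func:`write_psi_table`.

    Unparseable PSI fields become missing cells; a duplicate event id or
    a sample column absent from the sample map is a hard error.
    """
    samples = (sample_map if isinstance(sample_map, SampleMap)
               else read_sample_map(sample_map))
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw["event_id"].duplicated().any():
        dups = raw.loc[raw["event_id"].duplicated(), "event_id"].tolist()
        raise ValueError(f"duplicate event ids in {path}: {dups}")
    psi_cols = [c for c in raw.columns
                if c not in _META_COLS and not c.endswith(".reads")]
    for c in psi_cols:
        if c not in samples.table.index:
            raise ValueError(f"sample {c!r} in table missing from sample map")
    events = [
        SpliceEvent(
            event_id=r["event_id"], gene_id=r["gene_id"],
            event_type=r["event_type"], chrom=r["chrom"],
            span_start=int(r["span_start"]), span_end=int(r["span_end"]),
            exon_start=int(r["exon_start"]), exon_end=int(r["exon_end"]),
            strand=r["strand"],
        )
        for _, r in raw.iterrows()
    ]
    idx = raw["event_id"]
    sids = samples.sample_ids

    def _parse(v: str) -> float:
        try:
            return float(v)
        except ValueError:
            return np.nan

    psi = pd.DataFrame(
        {sid: raw[sid].map(_parse).to_numpy() for sid in sids}, index=idx)
    reads = pd.DataFrame(
        {sid: pd.to_numeric(raw[f"{sid}.reads"]).astype(int).to_numpy()
         for sid in sids}, index=idx)
    return PsiTable.build(events, samples, psi, reads, min_reads=min_reads)


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

@dataclass
class ExprTable:
    """Genes × samples expression matrix with a unit tag.

    ``is_subset`` marks a table whose rows were filtered out of a full
    library; its cpm values still refer to the original library size,
    so the column-sum invariant is not enforced on it.
    """

    values: pd.DataFrame
    samples: SampleMap
    unit: str  # counts | cpm | tpm | scaled
    is_subset: bool = False

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "cpm", "tpm", "scaled"):
            raise ValueError(f"bad unit {self.unit!r}")
        if list(self.values.columns) != self.samples.sample_ids:
            raise ValueError("value columns do not match sample map")
        if self.unit != "scaled" and (self.values.to_numpy() < 0).any():
            raise ValueError(f"negative values in a {self.unit} table")
        if self.unit == "cpm" and not self.is_subset:
            sums = self.values.sum(axis=0).to_numpy(float)
            if not np.allclose(sums, 1e6, rtol=1e-6):
                raise ValueError("cpm columns do not sum to 1e6")
        if self.unit == "scaled":
            v = self.values.to_numpy(float)
            if v.shape[1] >= 2:
                if not (np.allclose(v.mean(axis=1), 0, atol=1e-9)
                        and np.allclose(v.std(axis=1, ddof=1), 1, atol=1e-9)):
                    raise ValueError("scaled rows must have mean 0, sd 1")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


def read_expr_table(path: str, sample_map: str | SampleMap,
                    unit: str = "counts") -> ExprTable:
    samples = (sample_map if isinstance(sample_map, SampleMap)
               else read_sample_map(sample_map))
    v = pd.read_csv(path, sep="\t", index_col=0)
    return ExprTable(v[samples.sample_ids], samples, unit)


def write_expr_table(e: ExprTable, path: str) -> str:
    e.values.to_csv(path, sep="\t", index_label="gene_id")
    return path


# ---------------------------------------------------------------------------
# transcript models
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """Exon structure plus CDS bounds of one transcript.

    ``exons`` are 0-based half-open genomic intervals ordered 5'→3' in
    transcript orientation. ``cds_start``/``cds_end`` are genomic
    (cds_start < cds_end regardless of strand); both are None for
    non-coding transcripts.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("bad strand")
        genomic = sorted(self.exons)
        for (a0, a1), (b0, b1) in zip(genomic, genomic[1:]):
            if b0 < a1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        expect = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != expect:
            raise ValueError(
                f"{self.transcript_id}: exons not in transcript orientation")
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError("half-specified CDS")
        if self.cds_start is not None:
            if self.cds_len % 3 != 0:
                raise ValueError(
                    f"{self.transcript_id}: CDS length {self.cds_len} not divisible by 3")

    @property
    def biotype(self) -> str:
        return "noncoding" if self.cds_start is None else "coding"

    @property
    def cds_len(self) -> int:
        if self.cds_start is None:
            return 0
        return sum(
            max(0, min(e1, self.cds_end) - max(e0, self.cds_start))
            for e0, e1 in self.exons)

    def genomic_exons(self) -> list[tuple[int, int]]:
        return sorted(self.exons)


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_transcript_models(path: str) -> list[TranscriptModel]:
    """Read transcript models from GTF-lite (exon/CDS lines) or BED12.

    GTF coordinates (1-based inclusive) are converted to 0-based
    half-open. A transcript whose CDS length is not divisible by 3 is
    dropped with a warning rather than aborting the read.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh
                 if ln.strip() and not ln.startswith("#")]
    if not lines:
        return []
    n_fields = len(lines[0].split("\t"))
    if n_fields == 12:
        return _read_bed12(lines)
    return _read_gtf_lite(lines)


def _read_gtf_lite(lines: list[str]) -> list[TranscriptModel]:
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    info: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    for ln in lines:
        f = ln.split("\t")
        if len(f) < 9:
            raise ValueError(f"malformed GTF line: {ln!r}")
        chrom, _src, feature, start, end, _score, strand, _frame, attr = f[:9]
        if feature not in ("exon", "CDS"):
            continue
        a = _parse_gtf_attributes(attr)
        tid = a["transcript_id"]
        gid = a.get("gene_id", tid)
        info.setdefault(tid, (gid, chrom, strand))
        iv = (int(start) - 1, int(end))  # 1-based inclusive -> half-open
        (exons if feature == "exon" else cds).setdefault(tid, []).append(iv)

    models: list[TranscriptModel] = []
    for tid, (gid, chrom, strand) in info.items():
        ex = sorted(exons.get(tid, []))
        if strand == "-":
            ex = ex[::-1]
        cs = ce = None
        if tid in cds:
            cs = min(s for s, _ in cds[tid])
            ce = max(e for _, e in cds[tid])
        try:
            models.append(TranscriptModel(tid, gid, chrom, strand, ex, cs, ce))
        except ValueError as err:
            warnings.warn(f"skipping transcript {tid}: {err}")
    return models


def _read_bed12(lines: list[str]) -> list[TranscriptModel]:
    models: list[TranscriptModel] = []
    for ln in lines:
        f = ln.split("\t")
        chrom, start, _end, name, _score, strand = f[0], int(f[1]), f[2], f[3], f[4], f[5]
        thick_s, thick_e = int(f[6]), int(f[7])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        ex = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
        if strand == "-":
            ex = ex[::-1]
        cs, ce = (None, None) if thick_s == thick_e else (thick_s, thick_e)
        gid = name.split(".")[0]
        try:
            models.append(TranscriptModel(name, gid, chrom, strand, ex, cs, ce))
        except ValueError as err:
            warnings.warn(f"skipping transcript {name}: {err}")
    return models


# ---------------------------------------------------------------------------
# poly-A usage tables
# ---------------------------------------------------------------------------

@dataclass
class PauTable:
    """Poly-A sites × samples usage matrix with transcript expression.

    ``sites`` is indexed by polyA_site_id with columns ``gene_id``,
    ``chrom``, ``start``, ``end`` (last-exon interval, half-open) and
    ``strand``. PAU values of one gene sum to ~100 per sample.
    """

    sites: pd.DataFrame
    samples: SampleMap
    pau: pd.DataFrame
    tpm: pd.DataFrame

    def __post_init__(self) -> None:
        if self.sites.index.has_duplicates:
            raise ValueError("duplicate polyA site ids")
        for m in (self.pau, self.tpm):
            if list(m.index) != list(self.sites.index):
                raise ValueError("matrix index does not match sites")
            if list(m.columns) != self.samples.sample_ids:
                raise ValueError("matrix columns do not match sample map")
        per_gene = self.pau.groupby(self.sites["gene_id"]).sum()
        if not np.allclose(per_gene.to_numpy(float), 100.0, atol=0.5):
            raise ValueError("PAU values of a gene do not sum to 100 ± 0.5")
        counts = self.sites.groupby("gene_id").size()
        if (counts < 2).any():
            bad = counts.index[counts < 2].tolist()
            raise ValueError(f"genes with < 2 polyA sites: {bad}")


def read_pau_table(path: str, sample_map: str | SampleMap) -> PauTable:
    samples = (sample_map if isinstance(sample_map, SampleMap)
               else read_sample_map(sample_map))
    raw = pd.read_csv(path, sep="\t").set_index("polyA_site_id")
    site_cols = ["gene_id", "chrom", "start", "end", "strand"]
    sids = samples.sample_ids
    pau = raw[[f"{s}.pau" for s in sids]].copy()
    pau.columns = sids
    tpm = raw[[f"{s}.tpm" for s in sids]].copy()
    tpm.columns = sids
    return PauTable(raw[site_cols], samples, pau, tpm)


def write_pau_table(p: PauTable, path: str) -> str:
    out = p.sites.copy()
    for s in p.samples.sample_ids:
        out[f"{s}.pau"] = p.pau[s]
        out[f"{s}.tpm"] = p.tpm[s]
    out.to_csv(path, sep="\t", index_label="polyA_site_id")
    return path


# ---------------------------------------------------------------------------
# sequences and BED
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]],
                path: str) -> str:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(records, path, "fasta")
    return path


def write_bed6(events: Sequence[SpliceEvent], path: str,
               use_span: bool = True) -> str:
    """Export event spans (or the alternative segment) as BED6."""
    with open(path, "w") as fh:
        for e in events:
            s, t = ((e.span_start, e.span_end) if use_span
                    else (e.exon_start, e.exon_end))
            fh.write(f"{e.chrom}\t{s}\t{t}\t{e.event_id}\t0\t{e.strand}\n")
    return path
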