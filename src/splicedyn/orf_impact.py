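"""Predicted impact of alternative exons on transcript coding potential.

Each cassette exon is classified against its host transcript(s):
exons in non-coding RNAs or untranslated regions are labelled as such;
ORF-mapping exons are tested by rebuilding the coding sequence with and
without the exon. The isoform that differs from the annotated one is
*disrupted* when the exon length is not a multiple of 3 (frameshift),
or when a premature termination codon (PTC) appears that either
triggers nonsense-mediated decay (PTC more than 50 nt upstream of the
last exon–exon junction, the standard NMD rule) or truncates the
protein by more than 300 amino acids. Everything else preserves the
ORF. The direction label (disrupt_on_inclusion / _on_exclusion) names
the isoform that carries the disruption.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from splicedyn.config import DEFAULTS
from splicedyn.core_io import TranscriptModel

CATEGORIES = ("disrupt_on_inclusion", "disrupt_on_exclusion",
              "orf_preserving", "ncRNA", "utr5", "utr3", "uncertain")
REASONS = ("frameshift", "ptc_nmd", "truncation_gt300", "none")


@dataclass(frozen=True)
class ImpactCall:
    event_id: str
    category: str
    reason: str = "none"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"bad category {self.category!r}")
        if self.reason not in REASONS:
            raise ValueError(f"bad reason {self.reason!r}")
        disrupting = self.category in ("disrupt_on_inclusion",
                                       "disrupt_on_exclusion")
        if disrupting != (self.reason != "none"):
            raise ValueError("reason set iff category is disrupting")


def spliced_seq(exons_tx_order: list[tuple[int, int]], chrom_seq: str,
                strand: str) -> str:
    """Mature mRNA sequence from exons given in transcript order."""
    parts = []
    for s, e in exons_tx_order:
        piece = chrom_seq[s:e]
        if strand == "-":
            piece = str(Seq(piece).reverse_complement())
        parts.append(piece)
    return "".join(parts)


def tx_coord(genomic_pos: int, exons_tx_order: list[tuple[int, int]],
             strand: str) -> int:
    """Transcript-coordinate offset of a genomic position inside an exon."""
    off = 0
    for s, e in exons_tx_order:
        if s <= genomic_pos < e:
            return off + (genomic_pos - s if strand == "+"
                          else (e - 1) - genomic_pos)
        off += e - s
    raise ValueError(f"position {genomic_pos} not exonic")


def locate_exon(exon: tuple[int, int], t: TranscriptModel) -> str:
    """Region of an alternative exon within a transcript.

    Returns ORF / utr5 / utr3 / ncRNA / uncertain. The exon must either
    equal one of the transcript's exons or fall inside one of its
    introns (a skippable segment); otherwise it cannot be matched and
    is uncertain. An exon straddling a CDS boundary counts as ORF.
    """
    if _isoform_exons(exon, t) is None:
        return "uncertain"
    if t.biotype == "noncoding":
        return "ncRNA"
    s, e = exon
    assert t.cds_start is not None and t.cds_end is not None
    if e <= t.cds_start:  # genomically left of the CDS
        return "utr5" if t.strand == "+" else "utr3"
    if s >= t.cds_end:    # genomically right of the CDS
        return "utr3" if t.strand == "+" else "utr5"
    return "ORF"


def _isoform_exons(exon: tuple[int, int], t: TranscriptModel,
                   ) -> tuple[list[tuple[int, int]], list[tuple[int, int]], str] | None:
    """Exon chains of the inclusion and exclusion isoforms.

    Returns (inclusion_exons, exclusion_exons, annotated_state), all in
    transcript order, or None when the exon matches neither an
    annotated exon nor an intronic (skippable) segment.
    """
    genomic = t.genomic_exons()
    if tuple(exon) in {tuple(iv) for iv in genomic}:
        excl = [iv for iv in genomic if tuple(iv) != tuple(exon)]
        incl = genomic
        annotated = "inclusion"
    else:
        s, e = exon
        inside_intron = any(a1 <= s and e <= b0 for (a0, a1), (b0, b1)
                            in zip(genomic, genomic[1:]))
        if not inside_intron:
            return None
        incl = sorted(genomic + [tuple(exon)])
        excl = genomic
        annotated = "exclusion"
    if t.strand == "-":
        incl, excl = incl[::-1], excl[::-1]
    return list(map(tuple, incl)), list(map(tuple, excl)), annotated


def _translate_from(mrna: str, cds_idx: int) -> tuple[str, int | None]:
    """Protein from cds_idx to the first stop; returns (aa, stop_nt_offset).

    ``stop_nt_offset`` is the offset of the stop codon start from
    cds_idx, or None when translation runs off the transcript end.
    """
    coding = mrna[cds_idx:]
    coding = coding[: len(coding) - len(coding) % 3]
    aa = str(Seq(coding).translate())
    stop = aa.find("*")
    if stop == -1:
        return aa, None
    return aa[:stop], 3 * stop


def predict_impact(exon: tuple[int, int], t: TranscriptModel,
                   chrom_seq: str,
                   truncation_aa: int = DEFAULTS["truncation_aa"],
                   nmd_rule_nt: int = DEFAULTS["nmd_rule_nt"],
                   event_id: str = "") -> ImpactCall:
    """Classify one exon against one transcript (with genome sequence)."""
    region = locate_exon(exon, t)
    if region != "ORF":
        return ImpactCall(event_id, region)
    iso = _isoform_exons(exon, t)
    assert iso is not None
    incl, excl, annotated = iso
    altered_exons = excl if annotated == "inclusion" else incl
    annot_exons = incl if annotated == "inclusion" else excl
    altered_state = "exclusion" if annotated == "inclusion" else "inclusion"

    assert t.cds_start is not None and t.cds_end is not None
    start_genomic = t.cds_start if t.strand == "+" else t.cds_end - 1
    try:
        annot_idx = tx_coord(start_genomic, annot_exons, t.strand)
        alt_idx = tx_coord(start_genomic, altered_exons, t.strand)
    except ValueError:
        # CDS start removed by the event itself
        return ImpactCall(event_id, "uncertain")

    annot_mrna = spliced_seq(annot_exons, chrom_seq, t.strand)
    alt_mrna = spliced_seq(altered_exons, chrom_seq, t.strand)
    ref_aa, _ = _translate_from(annot_mrna, annot_idx)
    alt_aa, alt_stop = _translate_from(alt_mrna, alt_idx)

    exon_len = exon[1] - exon[0]
    if exon_len % 3 != 0:
        reason = "frameshift"
    else:
        # same frame: disruption only via an introduced in-frame PTC
        if alt_stop is None or len(alt_aa) >= len(ref_aa):
            return ImpactCall(event_id, "orf_preserving")
        stop_pos = alt_idx + alt_stop  # stop codon start, mRNA coords
        last_junction = sum(e1 - e0 for e0, e1 in altered_exons[:-1])
        if len(altered_exons) >= 2 and last_junction - stop_pos > nmd_rule_nt:
            reason = "ptc_nmd"
        elif len(ref_aa) - len(alt_aa) > truncation_aa:
            reason = "truncation_gt300"
        else:
            return ImpactCall(event_id, "orf_preserving")
    category = ("disrupt_on_inclusion" if altered_state == "inclusion"
                else "disrupt_on_exclusion")
    return ImpactCall(event_id, category, reason)


def classify_event(exon: tuple[int, int], transcripts: list[TranscriptModel],
                   genome: dict[str, str],
                   truncation_aa: int = DEFAULTS["truncation_aa"],
                   nmd_rule_nt: int = DEFAULTS["nmd_rule_nt"],
                   event_id: str = "") -> ImpactCall:
    """Classify against every host transcript; majority category wins.

    Ties (or no classifiable transcript) yield ``uncertain``. The
    reason reported is the most common reason among transcripts voting
    for the winning category.
    """
    calls = [predict_impact(exon, t, genome[t.chrom], truncation_aa,
                            nmd_rule_nt, event_id)
             for t in transcripts if t.chrom in genome]
    calls = [c for c in calls if c.category != "uncertain"]
    if not calls:
        return ImpactCall(event_id, "uncertain")
    counts = Counter(c.category for c in calls).most_common()
    if len(counts) > 1 and counts[0][1] == counts[1][1]:
        return ImpactCall(event_id, "uncertain")
    winner = counts[0][0]
    reasons = Counter(c.reason for c in calls if c.category == winner)
    return ImpactCall(event_id, winner, reasons.most_common(1)[0][0])


def impact_enrichment(calls_by_cluster: dict[str, list[ImpactCall]],
                      background: list[ImpactCall]) -> pd.DataFrame:
    """Per-cluster category fractions with Fisher enrichment p-values.

    Each (cluster, category) cell is tested 2×2 against the background
    distribution: category vs rest × in-cluster vs background. Empty
    clusters are skipped with a warning.
    """
    import warnings

    if not background:
        raise ValueError("empty background")
    bg = Counter(c.category for c in background)
    n_bg = len(background)
    rows = []
    for cluster, calls in calls_by_cluster.items():
        if not calls:
            warnings.warn(f"cluster {cluster!r} is empty; skipped")
            continue
        n = len(calls)
        cnt = Counter(c.category for c in calls)
        for cat in CATEGORIES:
            a = cnt.get(cat, 0)
            b = bg.get(cat, 0)
            _, p = stats.fisher_exact([[a, n - a], [b, n_bg - b]])
            rows.append({"cluster": cluster, "category": cat,
                         "fraction": a / n, "background_fraction": b / n_bg,
                         "n": n, "p": float(p)})
    return pd.DataFrame(rows)
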