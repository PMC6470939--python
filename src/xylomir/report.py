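"""Report tables and the keyword-based functional-bin summary.

GO-enrichment / pathway-mapping services are deliberately out of scope;
gene annotation texts are binned by a fixed ordered keyword table whose
vocabulary mirrors the functional groups commonly reported for heavy
metal-responsive miRNA targets (abiotic stress, phytohormone, secondary
metabolism, metal handling, transcription factors, signaling)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

__all__ = ["FunctionalBin", "DEFAULT_KEYWORDS", "BINS", "assign_bins"]

BINS = (
    "Abiotic stress",
    "Phytohormone",
    "Secondary metabolism",
    "Metal handling",
    "Transcription factors",
    "Signaling",
    "Other",
)

# ordered: the first matching lowercase substring wins
DEFAULT_KEYWORDS: tuple[tuple[str, str], ...] = (
    ("laccase", "Secondary metabolism"),
    ("mate efflux", "Metal handling"),
    ("major facilitator", "Metal handling"),
    ("heavy-metal", "Metal handling"),
    ("heavy metal", "Metal handling"),
    ("abc transporter", "Metal handling"),
    ("metal", "Metal handling"),
    ("myb", "Transcription factors"),
    ("wrky", "Transcription factors"),
    ("nac-", "Transcription factors"),
    ("bhlh", "Transcription factors"),
    ("homeobox", "Transcription factors"),
    ("ap2-erebp", "Transcription factors"),
    ("zinc finger", "Transcription factors"),
    ("transcription factor", "Transcription factors"),
    ("squamosa promoter binding", "Transcription factors"),
    ("gras", "Transcription factors"),
    ("nuclear transcription factor", "Transcription factors"),
    ("auxin", "Phytohormone"),
    ("aldehyde oxidase", "Phytohormone"),
    ("f-box", "Phytohormone"),
    ("dnaj", "Abiotic stress"),
    ("early-responsive to dehydration", "Abiotic stress"),
    ("erd", "Abiotic stress"),
    ("wound-responsive", "Abiotic stress"),
    ("heat", "Abiotic stress"),
    ("methyltransferase", "Abiotic stress"),
    ("isopentenyl", "Secondary metabolism"),
    ("calcium", "Signaling"),
    ("calcineurin", "Signaling"),
    ("calmodulin", "Signaling"),
    ("cam-binding", "Signaling"),
    ("kinase", "Signaling"),
    ("iq-domain", "Signaling"),
    ("phosphatase", "Signaling"),
)


@dataclass
class FunctionalBin:
    gene_id: str
    bin: str


def assign_bins(
    gene_annotations: Mapping[str, str],
    keyword_table: Sequence[tuple[str, str]] = DEFAULT_KEYWORDS,
) -> list[FunctionalBin]:
    """One bin per gene, a pure function of its annotation text: the
    first keyword (in table order) found as a lowercase substring wins;
    no match -> Other."""
    out = []
    for gene in sorted(gene_annotations):
        text = gene_annotations[gene].lower()
        chosen = "Other"
        for kw, bin_ in keyword_table:
            if kw in text:
                chosen = bin_
                break
        out.append(FunctionalBin(gene_id=gene, bin=chosen))
    return out
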