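"""m6A-associated motif scanning and hypergeometric enrichment.

Two degenerate patterns are scanned on cDNA (DNA alphabet, U written as
T): RRACH (``[GA][GA]AC[TAC]``), the consensus around m6A methylation
sites, and URUAY (``T[GA]TA[TA]``), the binding motif of YTH-domain m6A
readers of the ECT2 family.  A gene carries a motif in a region (whole
mRNA or 3'UTR) when any of its transcripts does; enrichment of a target
gene set against a background is the upper-tail hypergeometric
probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MOTIFS = {
    "RRACH": "[GA][GA]AC[TAC]",
    "URUAY": "T[GA]TA[TA]",
}

_CLASSES = {
    "RRACH": ("GA", "GA", "A", "C", "TAC"),
    "URUAY": ("T", "GA", "T", "A", "TA"),
}


class MotifError(ValueError):
    pass


@dataclass
class MotifReport:
    """Enrichment of one motif in one region for a target gene set."""

    motif_name: str
    region: str
    target_present: int
    target_total: int
    background_present: int
    background_total: int
    p_enrich: float


def scan_motif(sequence: str, motif_name: str) -> list[int]:
    """All (possibly overlapping) 0-based match starts of a motif.

    Character-class matching over {A, C, G, T}; ``N`` (or any other
    letter) never matches.  The scan slides one base at a time, so
    overlapping occurrences are all reported.
    """
    if motif_name not in _CLASSES:
        raise MotifError(f"unknown motif {motif_name!r}; know {sorted(_CLASSES)}")
    classes = _CLASSES[motif_name]
    seq = sequence.upper()
    k = len(classes)
    hits = []
    for i in range(len(seq) - k + 1):
        if all(seq[i + j] in classes[j] for j in range(k)):
            hits.append(i)
    return hits


def gene_motif_presence(
    transcripts: dict,
    motif_name: str,
    region: str = "mrna",
    utr3_lens: dict | None = None,
) -> bool:
    """True iff any transcript of the gene matches the motif in the region.

    ``transcripts`` maps transcript id to its cDNA sequence.  For
    ``region='3utr'`` the last ``utr3_lens[tx_id]`` bases of each
    transcript are scanned; a transcript without a 3'UTR length
    contributes nothing and triggers a warning.
    """
    region = region.lower().replace("'", "")
    if region not in ("mrna", "3utr"):
        raise MotifError(f"unknown region {region!r}")
    for tx_id, seq in transcripts.items():
        if region == "3utr":
            u3 = (utr3_lens or {}).get(tx_id)
            if not u3:
                warnings.warn(f"transcript {tx_id} has no 3'UTR annotation")
                continue
            seq = seq[-int(u3):]
        if scan_motif(seq, motif_name):
            return True
    return False


def hypergeom_enrichment(k: int, n: int, K_bg: int, N_bg: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    ``k`` of ``n`` drawn genes carry the motif, out of ``K_bg`` carriers
    among ``N_bg`` genes in total.
    """
    if not (0 <= k <= n <= N_bg and k <= K_bg <= N_bg):
        raise MotifError(
            f"inconsistent counts k={k}, n={n}, K_bg={K_bg}, N_bg={N_bg}"
        )
    return float(stats.hypergeom.sf(k - 1, N_bg, K_bg, n))


def motif_enrichment_report(
    gene_transcripts: dict,
    target_genes: set,
    motif_name: str,
    region: str = "mrna",
    utr3_lens: dict | None = None,
    background_genes: set | None = None,
) -> MotifReport:
    """Presence counts and enrichment p for a target set vs the background.

    ``gene_transcripts`` maps gene id -> {transcript id: sequence}.  The
    background defaults to every gene with sequence; the target set is
    tested against that universe.
    """
    universe = set(gene_transcripts) if background_genes is None \
        else set(background_genes)
    targets = set(target_genes) & universe
    present = {
        g for g in universe
        if gene_motif_presence(gene_transcripts[g], motif_name, region, utr3_lens)
    }
    k = len(targets & present)
    p = hypergeom_enrichment(k, len(targets), len(present), len(universe))
    return MotifReport(
        motif_name=motif_name,
        region=region,
        target_present=k,
        target_total=len(targets),
        background_present=len(present),
        background_total=len(universe),
        p_enrich=p,
    )


def reports_to_frame(reports: list[MotifReport]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in reports])
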