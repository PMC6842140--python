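"""Intron-level accuracy against a reference annotation.

The prediction is the set of introns induced by spliced alignments; the
reference is the set of introns between consecutive CDS features of each
transcript (coding introns are annotated more reliably than UTR or non-coding
ones).  Both are plain coordinate sets — each intron counted once — and

* sensitivity = |predicted ∩ reference| / |reference|
* specificity = |predicted ∩ reference| / |predicted|.

The cumulative accuracy curve reports both measures as a function of the
number of downloaded spots, in download order: sensitivity can only grow
(unions of introns only grow), while specificity typically decays as rare
false junctions accumulate.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .introns import IntronSet

logger = logging.getLogger(__name__)


def reference_coding_introns(annotation_path) -> IntronSet:
    """Introns between consecutive CDS features of each transcript of a GFF3.

    CDS features are grouped by their ``Parent`` attribute (fallback:
    ``transcript_id``, then ``gene_id``); per transcript, consecutive CDS
    intervals sorted by coordinate yield introns ``(end_i+1, start_{i+1}-1)``.
    Introns are deduplicated across transcripts and genes; transcripts with
    overlapping CDS parts are skipped with a warning; abutting CDS (zero gap)
    yield no intron.
    """
    from gffutils.iterators import DataIterator

    groups: dict = {}
    for feature in DataIterator(str(annotation_path)):
        if feature.featuretype != "CDS":
            continue
        parents = feature.attributes.get("Parent")
        if not parents:
            parents = (feature.attributes.get("transcript_id")
                       or feature.attributes.get("gene_id"))
        if not parents:
            logger.warning("CDS at %s:%d-%d has no Parent/transcript_id/gene_id; skipped",
                           feature.seqid, feature.start, feature.end)
            continue
        for parent in parents:
            groups.setdefault((feature.seqid, parent), []).append(
                (feature.start, feature.end)
            )

    out = IntronSet()
    for (seqid, parent), intervals in groups.items():
        intervals.sort()
        overlapping = any(s2 <= e1 for (_, e1), (s2, _) in zip(intervals, intervals[1:]))
        if overlapping:
            logger.warning("transcript %s on %s has overlapping CDS parts; skipped",
                           parent, seqid)
            continue
        for (_, e1), (s2, _) in zip(intervals, intervals[1:]):
            if s2 - 1 >= e1 + 1:
                key = (seqid, e1 + 1, s2 - 1)
                if key not in out:
                    out.add(*key)
    return out


def intron_accuracy(predicted: IntronSet, reference: IntronSet) -> Tuple[float, float]:
    """Sensitivity and specificity of a predicted intron set.

    Raises :class:`ValueError` on an empty reference (sensitivity undefined);
    an empty prediction gives sensitivity 0 and specificity ``nan``.
    """
    if len(reference) == 0:
        raise ValueError("reference intron set is empty: sensitivity is undefined")
    if len(predicted) == 0:
        return 0.0, math.nan
    hits = len(predicted.keys() & reference.keys())
    return hits / len(reference), hits / len(predicted)


def accuracy_curve(batches: Sequence, reference: IntronSet) -> pd.DataFrame:
    """Cumulative intron accuracy after each batch, in download order.

    ``batches`` are :class:`~rnascout.accounting.BatchResult` objects; the
    prediction after batch *k* is the union of introns observed in batches
    1..k, and the x-coordinate is the cumulative number of *downloaded* spots
    (not aligned ones).  Returns a table with columns
    ``spots, n_predicted, sensitivity, specificity``.
    """
    rows: List[tuple] = []
    cumulative = IntronSet()
    spots = 0
    for batch in batches:
        spots += batch.spots_downloaded
        cumulative.update(batch.introns_observed)
        sn, sp = intron_accuracy(cumulative, reference)
        rows.append((spots, len(cumulative), sn, sp))
    return pd.DataFrame(rows, columns=["spots", "n_predicted", "sensitivity", "specificity"])


def write_intron_hints(introns: IntronSet, path, source: str = "rnascout") -> None:
    """GFF-style intron hints (coordinates + support), one line per intron."""
    frame = introns.to_frame()
    with open(path, "w") as handle:
        for row in frame.itertuples(index=False):
            handle.write(
                f"{row.sequence}\t{source}\tintron\t{row.start}\t{row.end}\t"
                f"{row.support}\t.\t.\tmult={row.support};src=E\n"
            )
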