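"""Writing alignment records as SAM/BAM via pysam."""

from __future__ import annotations

from typing import Iterable, Sequence, Tuple

import pysam

from .accounting import AlignmentRecord


def _to_pysam(record: AlignmentRecord, header: pysam.AlignmentHeader) -> pysam.AlignedSegment:
    aln = pysam.AlignedSegment(header)
    aln.query_name = record.qname
    flag = 0
    if record.is_paired:
        flag |= 0x1 | (0x40 if record.is_first else 0x80)
        if not record.mate_mapped:
            flag |= 0x8
    if not record.is_mapped:
        flag |= 0x4
    if record.is_reverse:
        flag |= 0x10
    if record.is_secondary:
        flag |= 0x100
    if record.is_supplementary:
        flag |= 0x800
    aln.flag = flag
    if record.is_mapped:
        aln.reference_id = header.get_tid(record.ref_name)
        aln.reference_start = record.pos - 1
        aln.mapping_quality = record.mapq
        aln.cigarstring = record.cigar
        if record.nh is not None:
            aln.set_tag("NH", int(record.nh))
    return aln


class AlignmentWriter:
    """Streams alignment records into a SAM (or BAM) file.

    With ``sort=True`` the output is coordinate-sorted on close (via
    samtools through pysam).
    """

    def __init__(self, path, sequences: Sequence[Tuple[str, int]], sort: bool = False):
        self.path = str(path)
        self.sort = sort
        self._tmp = self.path + ".unsorted" if sort else self.path
        mode = "wb" if self._tmp.endswith(".bam") else "w"
        self._header = pysam.AlignmentHeader.from_references(
            [name for name, _ in sequences], [length for _, length in sequences]
        )
        self._handle = pysam.AlignmentFile(self._tmp, mode, header=self._header)

    def write_batch(self, records: Iterable[AlignmentRecord]) -> None:
        for record in records:
            self._handle.write(_to_pysam(record, self._header))

    def close(self) -> None:
        self._handle.close()
        if self.sort:
            import os

            pysam.sort("-o", self.path, self._tmp)
            os.remove(self._tmp)

    def __enter__(self) -> "AlignmentWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()
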