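"""Run catalogue and the select → fetch → classify → account loop.

Each candidate sequencing run carries static metadata (pairedness, average
read length, total spot count) and dynamic state: the disjoint half-open spot
intervals already downloaded, a permanent blacklist flag, and cumulative
quality statistics.  The driver repeatedly picks a run (greedily, or
uniformly at random as a baseline), requests the lowest not-yet-downloaded
spot range of at most one batch, classifies the returned alignments, applies
the first-batch quality filter, and folds the batch into the coverage state.
No spot is ever requested twice; with an unlimited budget every spot of every
keepable run is eventually requested exactly once.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Protocol, Sequence, Tuple

import numpy as np
import pandas as pd

from .accounting import AlignmentRecord, BatchResult, FilterDecision, classify_batch, quality_filter
from .model import (
    ArchiveExhausted,
    CoverageState,
    RunQuality,
    SelectionParams,
    choose_next_run,
    score,
    update_state,
)
from .tiles import TileIndex

logger = logging.getLogger(__name__)

# consecutive adapter failures after which a run is abandoned
MAX_CONSECUTIVE_FAILURES = 3

RUNLIST_COLUMNS = ["run_id", "paired", "avg_read_length", "total_spots"]


class FetchError(RuntimeError):
    """Signalled by a fetch source when a batch cannot be retrieved/aligned."""


@dataclass
class FetchResult:
    """Alignment records of one batch plus the spot count actually retrieved."""

    records: List[AlignmentRecord]
    spots_retrieved: int


class FetchSource(Protocol):
    """Contract for batch retrieval: the loop never inspects how records
    were produced (external tools or simulator)."""

    def fetch(self, run: "RunRecord", interval: Tuple[int, int]) -> FetchResult:
        """Return alignments for spot interval ``[start, end)`` of ``run``;
        may return fewer spots than requested (run shorter than catalogued);
        raises :class:`FetchError` on failure."""
        ...


@dataclass
class RunRecord:
    """One candidate sequencing run: metadata plus download bookkeeping."""

    run_id: str
    paired: bool = False
    avg_read_length: Optional[float] = None
    total_spots: Optional[int] = None
    downloaded: List[Tuple[int, int]] = field(default_factory=list)
    blacklisted: bool = False
    consecutive_failures: int = 0
    _ended: bool = field(default=False, repr=False)

    def spots_downloaded(self) -> int:
        return sum(e - s for s, e in self.downloaded)

    @property
    def exhausted(self) -> bool:
        if self._ended:
            return True
        if self.total_spots is None:
            return False
        return self.spots_downloaded() >= self.total_spots

    def next_range(self, b: int) -> Tuple[int, int]:
        """Lowest-starting not-yet-downloaded interval of length <= b."""
        if b < 1:
            raise ValueError("batch size must be >= 1")
        if self.exhausted:
            raise ValueError(f"run {self.run_id} is exhausted")
        cursor = 0
        for start, end in self.downloaded:
            if start > cursor:  # gap before this interval
                return (cursor, min(cursor + b, start))
            cursor = max(cursor, end)
        upper = cursor + b if self.total_spots is None else min(cursor + b, self.total_spots)
        if upper <= cursor:
            raise ValueError(f"run {self.run_id} has no spots left")
        return (cursor, upper)

    def commit_range(self, start: int, end: int) -> None:
        """Record ``[start, end)`` as downloaded; intervals must stay disjoint."""
        if end <= start or start < 0:
            raise ValueError(f"bad interval [{start}, {end})")
        for s, e in self.downloaded:
            if start < e and s < end:
                raise AssertionError(
                    f"run {self.run_id}: interval [{start},{end}) overlaps downloaded [{s},{e})"
                )
        self.downloaded.append((start, end))
        self.downloaded.sort()

    def mark_ended(self, total: int) -> None:
        """Adapter reported the run ends at ``total`` spots (short download)."""
        self.total_spots = total
        self._ended = True


def load_runlist(path) -> List[RunRecord]:
    """Read a headered TSV run list (run_id, paired, avg_read_length, total_spots)."""
    df = pd.read_csv(path, sep="\t", dtype={"run_id": str})
    missing = [c for c in RUNLIST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"run list misses columns: {missing}")
    if df["run_id"].duplicated().any():
        raise ValueError("run list contains duplicate run ids")
    runs = []
    for row in df.itertuples(index=False):
        length = row.avg_read_length
        total = row.total_spots
        runs.append(
            RunRecord(
                run_id=str(row.run_id),
                paired=bool(int(row.paired)),
                avg_read_length=None if pd.isna(length) else float(length),
                total_spots=None if pd.isna(total) else int(total),
            )
        )
    return runs


def write_runlist(runs: Sequence[RunRecord], path) -> None:
    pd.DataFrame(
        [(r.run_id, int(r.paired), r.avg_read_length, r.total_spots) for r in runs],
        columns=RUNLIST_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


@dataclass
class LoopResult:
    """Outcome of a sampling session."""

    state: CoverageState
    runs: List[RunRecord]
    batch_log: pd.DataFrame
    summary: dict
    batches: List[BatchResult] = field(default_factory=list)


_LOG_COLUMNS = [
    "batch", "run_id", "range_start", "range_end", "spots_downloaded",
    "unique", "multi", "unmapped", "spliced", "blacklisted", "failed", "score",
]


def _eligible(runs: Sequence[RunRecord]) -> List[RunRecord]:
    return [r for r in runs if not r.blacklisted and not r.exhausted]


def _process_batch(
    run: RunRecord,
    interval: Tuple[int, int],
    source: FetchSource,
    tiles: TileIndex,
    params: SelectionParams,
    state: CoverageState,
    log_rows: list,
    batches: List[BatchResult],
    batch_no: int,
    alignment_sink: Optional[Callable[[List[AlignmentRecord]], None]],
) -> None:
    start, end = interval
    try:
        fetched = source.fetch(run, interval)
    except FetchError as exc:
        run.consecutive_failures += 1
        logger.warning("fetch failed for %s [%d,%d): %s", run.run_id, start, end, exc)
        if run.consecutive_failures >= MAX_CONSECUTIVE_FAILURES:
            run.blacklisted = True
            logger.warning("run %s blacklisted after %d consecutive failures",
                           run.run_id, run.consecutive_failures)
        log_rows.append([batch_no, run.run_id, start, end, 0, 0, 0, 0, 0,
                         int(run.blacklisted), 1, score(state.c)])
        return
    run.consecutive_failures = 0
    retrieved = fetched.spots_retrieved
    if retrieved < end - start:
        run.mark_ended(start + retrieved)
    if retrieved > 0:
        run.commit_range(start, start + retrieved)
    first_batch = run.run_id not in state.quality
    batch = classify_batch(run.run_id, fetched.records, retrieved, tiles)
    blacklist_now = False
    if first_batch:
        decision = quality_filter(batch, params.blacklist_threshold)
        blacklist_now = decision is FilterDecision.BLACKLIST
    if blacklist_now:
        # low-alignability run: permanently ignored, its first batch is
        # discarded so it contributes nothing to coverage or introns
        run.blacklisted = True
        quality = state.quality.setdefault(run.run_id, RunQuality())
        quality.n_sampled += batch.spots_downloaded
        quality.n_unique += batch.spots_unique
        quality.n_spliced += batch.spots_spliced
    else:
        update_state(state, run.run_id, batch)
        batches.append(batch)
        if alignment_sink is not None:
            alignment_sink(fetched.records)
    log_rows.append([
        batch_no, run.run_id, start, start + retrieved, retrieved,
        batch.spots_unique, batch.spots_multi, batch.spots_unmapped,
        batch.spots_spliced, int(run.blacklisted), 0, score(state.c),
    ])


def _finish(
    state: CoverageState,
    runs: Sequence[RunRecord],
    params: SelectionParams,
    log_rows: list,
    batches: List[BatchResult],
    mode: str,
) -> LoopResult:
    log = pd.DataFrame(log_rows, columns=_LOG_COLUMNS)
    summary = {
        "mode": mode,
        "batches_attempted": len(log_rows),
        "batches_failed": int(log["failed"].sum()) if len(log) else 0,
        "spots_downloaded": int(log["spots_downloaded"].sum()) if len(log) else 0,
        "spots_unique": int(log["unique"].sum()) if len(log) else 0,
        "spots_spliced": int(log["spliced"].sum()) if len(log) else 0,
        "runs_sampled": int(len({r for r in log["run_id"]})) if len(log) else 0,
        "runs_blacklisted": sum(1 for r in runs if r.blacklisted),
        "runs_exhausted": sum(1 for r in runs if r.exhausted),
        "final_score": score(state.c),
        "tiles_covered": int((state.c > 0).sum()),
        "n_tiles": state.n_tiles,
        "params": {
            "b": params.b, "lambda": params.lambda_, "a": params.a,
            "max_batches": params.max_batches,
            "q_weights": list(params.q_weights),
            "blacklist_threshold": params.blacklist_threshold,
            "tie_rel_tol": params.tie_rel_tol,
            "initial_q_hat": params.initial_q_hat,
            "seed": params.seed,
        },
    }
    return LoopResult(state=state, runs=list(runs), batch_log=log, summary=summary,
                      batches=batches)


def run_loop(
    runs: Sequence[RunRecord],
    tiles: TileIndex,
    params: SelectionParams,
    source: FetchSource,
    policy: str = "greedy",
    state: Optional[CoverageState] = None,
    alignment_sink: Optional[Callable[[List[AlignmentRecord]], None]] = None,
) -> LoopResult:
    """Run the online sampling loop for at most ``params.max_batches`` batches.

    ``policy`` is ``"greedy"`` (expected-score maximisation) or ``"random"``
    (uniform over eligible runs, a baseline).  A pre-existing ``state`` (e.g.
    from :func:`load_all_once`) is continued; range bookkeeping carries over
    so no spot is downloaded twice across phases.
    """
    if policy not in ("greedy", "random"):
        raise ValueError(f"unknown policy {policy!r}")
    if not runs:
        raise ValueError("run list is empty")
    rng = np.random.default_rng(params.seed)
    if state is None:
        state = CoverageState(len(tiles))
    log_rows: list = []
    batches: List[BatchResult] = []
    for batch_no in range(params.max_batches):
        candidates = _eligible(runs)
        if not candidates:
            break
        if policy == "greedy":
            try:
                run_id = choose_next_run(candidates, state, params, rng)
            except ArchiveExhausted:
                break
            run = next(r for r in candidates if r.run_id == run_id)
        else:
            run = candidates[int(rng.integers(len(candidates)))]
        interval = run.next_range(params.b)
        _process_batch(run, interval, source, tiles, params, state,
                       log_rows, batches, batch_no, alignment_sink)
    return _finish(state, runs, params, log_rows, batches, mode=f"loop:{policy}")


def load_all_once(
    runs: Sequence[RunRecord],
    tiles: TileIndex,
    params: SelectionParams,
    source: FetchSource,
    shuffle: bool = False,
    state: Optional[CoverageState] = None,
    alignment_sink: Optional[Callable[[List[AlignmentRecord]], None]] = None,
) -> LoopResult:
    """Trivial sampling: one batch from every run, bypassing greedy selection.

    Runs are visited in list order, or in a seeded random order when
    ``shuffle`` is set.  Accounting (classification, quality filter, range
    bookkeeping) is identical to :func:`run_loop`, so a subsequent greedy
    phase started from the returned state never re-downloads a spot.
    """
    if not runs:
        raise ValueError("run list is empty")
    rng = np.random.default_rng(params.seed)
    order = list(runs)
    if shuffle:
        order = [order[i] for i in rng.permutation(len(order))]
    if state is None:
        state = CoverageState(len(tiles))
    log_rows: list = []
    batches: List[BatchResult] = []
    batch_no = 0
    for run in order:
        if run.blacklisted or run.exhausted:
            continue
        interval = run.next_range(params.b)
        _process_batch(run, interval, source, tiles, params, state,
                       log_rows, batches, batch_no, alignment_sink)
        batch_no += 1
    return _finish(state, runs, params, log_rows, batches, mode="loadAllOnce")


class ExternalAlignerSource:
    """Fetch-and-align adapter calling fastq-dump and HISAT2/STAR.

    This is the contract implementation for real archives: spot ranges are
    retrieved with ``fastq-dump -N/-X`` and aligned with the chosen spliced
    aligner; the resulting SAM is converted to alignment records.  It requires
    the external executables on PATH and network access, and is exercised
    manually, not by the test suite.
    """

    def __init__(self, genome_index: str, aligner: str = "hisat2",
                 workdir: str = ".", threads: int = 1):
        if aligner not in ("hisat2", "star"):
            raise ValueError(f"unsupported aligner {aligner!r}")
        self.genome_index = genome_index
        self.aligner = aligner
        self.workdir = workdir
        self.threads = threads

    def _require(self, executable: str) -> str:
        path = shutil.which(executable)
        if path is None:
            raise FetchError(f"required executable {executable!r} not found on PATH")
        return path

    def fetch(self, run: RunRecord, interval: Tuple[int, int]) -> FetchResult:
        import os

        import pysam

        start, end = interval
        fastq_dump = self._require("fastq-dump")
        aligner = self._require("hisat2" if self.aligner == "hisat2" else "STAR")
        prefix = os.path.join(self.workdir, f"{run.run_id}_{start}_{end}")
        # fastq-dump spot ids are 1-based inclusive
        cmd = [fastq_dump, "-N", str(start + 1), "-X", str(end),
               "--split-files" if run.paired else "--skip-technical",
               "-O", self.workdir, "--defline-seq", "@$ac.$si", run.run_id]
        try:
            subprocess.run(cmd, check=True, capture_output=True)
        except subprocess.CalledProcessError as exc:
            raise FetchError(f"fastq-dump failed: {exc.stderr.decode(errors='replace')[:500]}")
        fq1 = os.path.join(self.workdir, f"{run.run_id}_1.fastq" if run.paired
                           else f"{run.run_id}.fastq")
        fq2 = os.path.join(self.workdir, f"{run.run_id}_2.fastq")
        sam_path = prefix + ".sam"
        if self.aligner == "hisat2":
            cmd = [aligner, "-x", self.genome_index, "-p", str(self.threads), "-S", sam_path]
            cmd += ["-1", fq1, "-2", fq2] if run.paired else ["-U", fq1]
        else:
            cmd = [aligner, "--genomeDir", self.genome_index, "--runThreadN", str(self.threads),
                   "--outSAMunmapped", "Within", "--outFileNamePrefix", prefix + ".",
                   "--readFilesIn", fq1] + ([fq2] if run.paired else [])
            sam_path = prefix + ".Aligned.out.sam"
        try:
            subprocess.run(cmd, check=True, capture_output=True)
        except subprocess.CalledProcessError as exc:
            raise FetchError(f"{self.aligner} failed: {exc.stderr.decode(errors='replace')[:500]}")
        records = []
        qnames = set()
        try:
            with pysam.AlignmentFile(sam_path, check_sq=False) as handle:
                for aln in handle:
                    records.append(AlignmentRecord.from_pysam(aln))
                    qnames.add(aln.query_name)
        except (OSError, ValueError) as exc:
            raise FetchError(f"unreadable aligner output: {exc}")
        if not records:
            raise FetchError("empty download")
        return FetchResult(records=records, spots_retrieved=len(qnames))
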