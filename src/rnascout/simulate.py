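"""Synthetic sequencing-run archive with ground truth.

Emulates the heterogeneity of a public read archive at desk scale: a random
genome carrying single-transcript gene models, and a catalogue of runs each
with its own multinomial expression profile over genes (drawn from a Dirichlet
whose small concentration yields tissue-like, highly skewed profiles).  A
configurable fraction of runs are defective: *low-alignability* runs whose
reads mostly fail to align uniquely (mimicking mislabeled species, miRNA
libraries, very short reads), and optionally *mislabeled-genomic* runs whose
reads are placed uniformly on the genome without splicing.

Reads are emitted as already-aligned records — CIGAR N operations appear
exactly where a read spans a true intron — so every downstream module can be
exercised without an aligner.  Everything is reproducible from the archive
seed: repeated requests for the same (run, spot interval) return identical
records regardless of request order, which the no-double-download bookkeeping
relies on.
"""

from __future__ import annotations

import dataclasses
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .accounting import AlignmentRecord
from .batches import FetchResult, RunRecord
from .introns import IntronSet
from .tiles import TileIndex

GOOD = "good"
LOW_ALIGNABILITY = "low-alignability"
MISLABELED_GENOMIC = "mislabeled-genomic"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class ConfigError(ValueError):
    """Infeasible or malformed archive configuration."""


@dataclass
class ArchiveConfig:
    """Study conditions of the synthetic archive.

    Lengths in bp; ``dirichlet_concentration`` < 1 gives sparse, skewed
    per-run expression profiles; ``bad_run_fraction`` of runs are
    low-alignability (``bad_unique_fraction`` of their reads align uniquely,
    the rest unmapped or multi-mapped).
    """

    seed: int = 0
    n_runs: int = 30
    n_genes: int = 200
    genome_length: int = 1_000_000
    n_sequences: int = 2
    exon_count_range: Tuple[int, int] = (2, 4)
    exon_length_range: Tuple[int, int] = (100, 300)
    intron_length_range: Tuple[int, int] = (60, 400)
    gene_gap_range: Tuple[int, int] = (200, 4000)
    read_length: int = 100
    paired: bool = False
    paired_gap: int = 100
    spots_per_run: int = 100_000
    dirichlet_concentration: float = 0.1
    bad_run_fraction: float = 0.2
    genomic_run_fraction: float = 0.0
    bad_unique_fraction: float = 0.03
    run_overrides: Dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_runs < 1 or self.n_genes < 1 or self.n_sequences < 1:
            raise ConfigError("n_runs, n_genes and n_sequences must be >= 1")
        if self.genome_length < self.n_sequences:
            raise ConfigError("genome shorter than the number of sequences")
        if not 0.0 <= self.bad_run_fraction <= 1.0:
            raise ConfigError("bad_run_fraction must be in [0, 1]")
        if not 0.0 <= self.genomic_run_fraction <= 1.0 - self.bad_run_fraction:
            raise ConfigError("quality-class fractions exceed 1")
        if not 0.0 <= self.bad_unique_fraction <= 1.0:
            raise ConfigError("bad_unique_fraction must be in [0, 1]")
        if self.read_length < 1 or self.spots_per_run < 1:
            raise ConfigError("read_length and spots_per_run must be >= 1")
        if self.dirichlet_concentration <= 0:
            raise ConfigError("dirichlet_concentration must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "ArchiveConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("exon_count_range", "exon_length_range",
                    "intron_length_range", "gene_gap_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        for key, value in data.items():
            if isinstance(value, tuple):
                data[key] = list(value)
        with open(path, "w") as handle:
            yaml.safe_dump(data, handle, sort_keys=True)


class GeneModel:
    """One single-transcript gene: ordered exons on one sequence."""

    __slots__ = ("gene_id", "seq_name", "strand", "exons", "_cum", "transcript_length", "_cigar_cache")

    def __init__(self, gene_id: str, seq_name: str, strand: str,
                 exons: Sequence[Tuple[int, int]]):
        exons = tuple((int(s), int(e)) for s, e in exons)
        if not exons:
            raise ConfigError("gene needs at least one exon")
        for (s, e), (s2, _) in zip(exons, exons[1:]):
            if s2 <= e:
                raise ConfigError("exons overlap or are unsorted")
        self.gene_id = gene_id
        self.seq_name = seq_name
        self.strand = strand
        self.exons = exons
        cum = [0]
        for s, e in exons:
            cum.append(cum[-1] + e - s + 1)
        self._cum = cum
        self.transcript_length = cum[-1]
        self._cigar_cache: Dict[Tuple[int, int], Tuple[int, str]] = {}

    @property
    def span(self) -> Tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def introns(self) -> List[Tuple[str, int, int]]:
        return [
            (self.seq_name, e + 1, s2 - 1)
            for (_, e), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    def genomic_position(self, t_pos: int) -> int:
        """1-based genomic coordinate of 0-based transcript position."""
        idx = bisect_right(self._cum, t_pos) - 1
        return self.exons[idx][0] + (t_pos - self._cum[idx])

    def cigar_for(self, t_start: int, length: int) -> Tuple[int, str]:
        """Leftmost genomic position and CIGAR of a read covering transcript
        interval ``[t_start, t_start + length)``."""
        key = (t_start, length)
        cached = self._cigar_cache.get(key)
        if cached is not None:
            return cached
        if t_start < 0 or t_start + length > self.transcript_length:
            raise ValueError("read interval outside transcript")
        idx = bisect_right(self._cum, t_start) - 1
        offset = t_start - self._cum[idx]
        pos = self.exons[idx][0] + offset
        parts: List[str] = []
        remaining = length
        while remaining > 0:
            exon_start, exon_end = self.exons[idx]
            available = exon_end - exon_start + 1 - offset
            take = min(available, remaining)
            parts.append(f"{take}M")
            remaining -= take
            if remaining > 0:
                next_start = self.exons[idx + 1][0]
                parts.append(f"{next_start - exon_end - 1}N")
                idx += 1
                offset = 0
        result = (pos, "".join(parts))
        self._cigar_cache[key] = result
        return result


@dataclass
class SimulatedRun:
    """Catalogue entry plus ground truth for one simulated run."""

    run_id: str
    index: int
    quality_class: str
    paired: bool
    read_length: int
    total_spots: int
    profile: np.ndarray  # true multinomial over genes


class SyntheticArchive:
    """A fully reproducible archive of simulated sequencing runs."""

    def __init__(self, config: ArchiveConfig, sequences, genes, runs):
        self.config = config
        self.sequences: Tuple[Tuple[str, int], ...] = tuple(sequences)
        self.genes: List[GeneModel] = list(genes)
        self.runs: List[SimulatedRun] = list(runs)
        self._by_id = {r.run_id: r for r in self.runs}
        self._seq_len = dict(self.sequences)

    # ---------------------------------------------------------------- truth

    def run(self, run_id: str) -> SimulatedRun:
        return self._by_id[run_id]

    def true_introns(self) -> IntronSet:
        out = IntronSet()
        for gene in self.genes:
            for intron in gene.introns():
                out.add(*intron)
        return out

    def run_list(self) -> List[RunRecord]:
        return [
            RunRecord(
                run_id=r.run_id,
                paired=r.paired,
                avg_read_length=float(r.read_length),
                total_spots=r.total_spots,
            )
            for r in self.runs
        ]

    def tile_index(self, tile_size: int = 5000) -> TileIndex:
        return TileIndex(self.sequences, tile_size=tile_size)

    def expressed_tiles(self, tiles: TileIndex, run_id: Optional[str] = None,
                        min_weight: float = 0.0) -> set:
        """Tiles overlapped by genes (optionally only genes with profile
        weight > min_weight in one run)."""
        profile = self._by_id[run_id].profile if run_id else None
        out = set()
        for g_idx, gene in enumerate(self.genes):
            if profile is not None and profile[g_idx] <= min_weight:
                continue
            start, end = gene.span
            out.update(tiles.tiles_of_interval(gene.seq_name, start - 1, end))
        return out

    def tile_profile(self, run_id: str, tiles: TileIndex) -> np.ndarray:
        """Exact tile-projection of a run's true profile: the distribution of
        the leftmost aligned base of a single-end read from that run."""
        run = self._by_id[run_id]
        out = np.zeros(len(tiles))
        for g_idx, gene in enumerate(self.genes):
            weight = run.profile[g_idx]
            if weight == 0.0:
                continue
            L = min(run.read_length, gene.transcript_length)
            n_starts = gene.transcript_length - L + 1
            per_start = weight / n_starts
            for t_start in range(n_starts):
                pos = gene.genomic_position(t_start)
                out[tiles.tile_of(gene.seq_name, pos - 1)] += per_start
        return out

    # ------------------------------------------------------------- sampling

    def _spot_rng(self, run: SimulatedRun, start: int) -> np.random.Generator:
        seed = np.random.SeedSequence(
            entropy=[int(self.config.seed) % (2**31), run.index, int(start)]
        )
        return np.random.default_rng(seed)

    def sample_batch(self, run_id: str, interval: Tuple[int, int]) -> List[AlignmentRecord]:
        """Alignment records for spot interval ``[start, end)`` of a run.

        Deterministic in (archive seed, run, interval start): re-requesting
        the same interval yields identical records.
        """
        run = self._by_id[run_id]
        start, end = interval
        if not 0 <= start < end <= run.total_spots:
            raise ValueError(f"interval [{start},{end}) outside run of {run.total_spots} spots")
        rng = self._spot_rng(run, start)
        n = end - start
        if run.quality_class == GOOD:
            return self._sample_good(run, n, start, rng)
        if run.quality_class == LOW_ALIGNABILITY:
            return self._sample_low(run, n, start, rng)
        if run.quality_class == MISLABELED_GENOMIC:
            return self._sample_genomic(run, n, start, rng)
        raise ValueError(f"unknown quality class {run.quality_class!r}")

    def _transcript_records(self, run: SimulatedRun, qname: str, gene: GeneModel,
                            rng: np.random.Generator, nh: int = 1,
                            mapq: int = 60) -> List[AlignmentRecord]:
        L = min(run.read_length, gene.transcript_length)
        if not run.paired:
            t_start = int(rng.integers(0, gene.transcript_length - L + 1))
            pos, cigar = gene.cigar_for(t_start, L)
            return [AlignmentRecord(qname, gene.seq_name, pos, cigar, nh=nh, mapq=mapq)]
        frag = min(2 * L + self.config.paired_gap, gene.transcript_length)
        t_start = int(rng.integers(0, gene.transcript_length - frag + 1))
        pos1, cigar1 = gene.cigar_for(t_start, L)
        pos2, cigar2 = gene.cigar_for(t_start + frag - L, L)
        return [
            AlignmentRecord(qname, gene.seq_name, pos1, cigar1, nh=nh, mapq=mapq,
                            is_paired=True, is_first=True),
            AlignmentRecord(qname, gene.seq_name, pos2, cigar2, nh=nh, mapq=mapq,
                            is_paired=True, is_first=False, is_reverse=True),
        ]

    def _sample_good(self, run, n, start, rng) -> List[AlignmentRecord]:
        gene_idx = rng.choice(len(self.genes), size=n, p=run.profile)
        records: List[AlignmentRecord] = []
        genes = self.genes
        run_id = run.run_id
        for i in range(n):
            qname = f"{run_id}.{start + i}"
            records.extend(self._transcript_records(run, qname, genes[gene_idx[i]], rng))
        return records

    def _sample_low(self, run, n, start, rng) -> List[AlignmentRecord]:
        # deterministic unique count so the first-batch filter behaves
        # identically across seeds at a given batch size
        n_unique = int(round(self.config.bad_unique_fraction * n))
        status = np.zeros(n, dtype=np.int8)  # 0 unmapped, 1 multi, 2 unique
        status[:n_unique] = 2
        status[n_unique : n_unique + (n - n_unique) // 2] = 1
        rng.shuffle(status)
        records: List[AlignmentRecord] = []
        for i in range(n):
            qname = f"{run.run_id}.{start + i}"
            if status[i] == 2:
                gene = self.genes[int(rng.choice(len(self.genes), p=run.profile))]
                records.extend(self._transcript_records(run, qname, gene, rng))
            elif status[i] == 1:
                gene = self.genes[int(rng.integers(len(self.genes)))]
                recs = self._transcript_records(run, qname, gene, rng, nh=2, mapq=1)
                records.extend(recs)
            else:
                records.append(AlignmentRecord(qname, None, 0, None,
                                               is_paired=run.paired, mate_mapped=False))
        return records

    def _sample_genomic(self, run, n, start, rng) -> List[AlignmentRecord]:
        lengths = np.array([length for _, length in self.sequences], dtype=float)
        seq_p = lengths / lengths.sum()
        records: List[AlignmentRecord] = []
        L = run.read_length
        for i in range(n):
            qname = f"{run.run_id}.{start + i}"
            s_idx = int(rng.choice(len(self.sequences), p=seq_p))
            name, length = self.sequences[s_idx]
            Li = min(L, length)
            pos = int(rng.integers(1, length - Li + 2))
            records.append(AlignmentRecord(qname, name, pos, f"{Li}M", nh=1, mapq=60,
                                           is_paired=run.paired))
        return records

    # --------------------------------------------------------------- export

    def sequence_bases(self, seq_index: int) -> bytes:
        """Deterministic random nucleotide sequence (generated on demand)."""
        name, length = self.sequences[seq_index]
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=[int(self.config.seed) % (2**31), 10**6, seq_index])
        )
        return _BASES[rng.integers(0, 4, size=length)].tobytes()

    def write_fasta(self, path) -> None:
        with open(path, "w") as handle:
            for i, (name, length) in enumerate(self.sequences):
                handle.write(f">{name}\n")
                seq = self.sequence_bases(i).decode()
                for j in range(0, length, 80):
                    handle.write(seq[j : j + 80] + "\n")

    def write_annotation_gff3(self, path) -> None:
        """Gene models as GFF3 (CDS spans the whole transcript)."""
        with open(path, "w") as handle:
            handle.write("##gff-version 3\n")
            for gene in self.genes:
                start, end = gene.span
                gid, tid = gene.gene_id, gene.gene_id + ".t1"
                handle.write(f"{gene.seq_name}\tsim\tgene\t{start}\t{end}\t.\t{gene.strand}\t.\tID={gid}\n")
                handle.write(f"{gene.seq_name}\tsim\tmRNA\t{start}\t{end}\t.\t{gene.strand}\t.\tID={tid};Parent={gid}\n")
                phase = 0
                for s, e in gene.exons:
                    handle.write(f"{gene.seq_name}\tsim\texon\t{s}\t{e}\t.\t{gene.strand}\t.\tParent={tid}\n")
                    handle.write(f"{gene.seq_name}\tsim\tCDS\t{s}\t{e}\t.\t{gene.strand}\t{phase}\tParent={tid}\n")
                    phase = (3 - ((e - s + 1 - phase) % 3)) % 3
        return None

    def write_truth(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.write_annotation_gff3(outdir / "genes.gff3")
        self.true_introns().to_tsv(outdir / "introns.tsv")
        import pandas as pd

        profiles = pd.DataFrame(
            {r.run_id: r.profile for r in self.runs},
            index=[g.gene_id for g in self.genes],
        )
        profiles.index.name = "gene_id"
        profiles.to_csv(outdir / "profiles.tsv", sep="\t")


def build_archive(config: ArchiveConfig) -> SyntheticArchive:
    """Materialise a synthetic archive from a configuration (deterministic)."""
    rng = np.random.default_rng(config.seed)
    base = config.genome_length // config.n_sequences
    sequences = [
        (f"chr{i + 1}", base + (config.genome_length % config.n_sequences if i == 0 else 0))
        for i in range(config.n_sequences)
    ]

    genes: List[GeneModel] = []
    seq_idx = 0
    cursor = 1
    lo_e, hi_e = config.exon_count_range
    for g in range(config.n_genes):
        n_exons = int(rng.integers(lo_e, hi_e + 1))
        exon_lens = rng.integers(config.exon_length_range[0],
                                 config.exon_length_range[1] + 1, size=n_exons)
        intron_lens = rng.integers(config.intron_length_range[0],
                                   config.intron_length_range[1] + 1,
                                   size=max(n_exons - 1, 0))
        gap = int(rng.integers(config.gene_gap_range[0], config.gene_gap_range[1] + 1))
        span = int(exon_lens.sum() + intron_lens.sum())
        placed = False
        while seq_idx < len(sequences):
            name, length = sequences[seq_idx]
            start = cursor + gap
            if start + span - 1 <= length:
                exons = []
                pos = start
                for k in range(n_exons):
                    exons.append((pos, pos + int(exon_lens[k]) - 1))
                    pos += int(exon_lens[k])
                    if k < n_exons - 1:
                        pos += int(intron_lens[k])
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(GeneModel(f"g{g + 1:04d}", name, strand, exons))
                cursor = start + span
                placed = True
                break
            seq_idx += 1
            cursor = 1
        if not placed:
            raise ConfigError(
                f"genome of {config.genome_length} bp too small for {config.n_genes} genes"
            )

    n_bad = int(round(config.bad_run_fraction * config.n_runs))
    n_genomic = int(round(config.genomic_run_fraction * config.n_runs))
    classes = ([LOW_ALIGNABILITY] * n_bad + [MISLABELED_GENOMIC] * n_genomic
               + [GOOD] * (config.n_runs - n_bad - n_genomic))
    classes = [classes[i] for i in rng.permutation(config.n_runs)]

    runs: List[SimulatedRun] = []
    alpha = np.full(config.n_genes, config.dirichlet_concentration)
    for i in range(config.n_runs):
        run_id = f"SIM{i + 1:04d}"
        profile = rng.dirichlet(alpha)
        settings = {
            "quality_class": classes[i],
            "paired": config.paired,
            "read_length": config.read_length,
            "total_spots": config.spots_per_run,
        }
        settings.update(config.run_overrides.get(run_id, {}))
        override_profile = settings.pop("profile", None)
        if override_profile is not None:
            profile = np.asarray(override_profile, dtype=float)
            if profile.shape != (config.n_genes,) or not np.isclose(profile.sum(), 1.0):
                raise ConfigError(f"bad profile override for {run_id}")
            profile = profile / profile.sum()
        runs.append(SimulatedRun(run_id=run_id, index=i, profile=profile, **settings))

    return SyntheticArchive(config, sequences, genes, runs)


class SimulatorSource:
    """Fetch-source adapter backed by a :class:`SyntheticArchive`."""

    def __init__(self, archive: SyntheticArchive):
        self.archive = archive

    def fetch(self, run: RunRecord, interval: Tuple[int, int]) -> FetchResult:
        start, end = interval
        total = self.archive.run(run.run_id).total_spots
        end = min(end, total)  # truncate at run end, report actual count
        records = self.archive.sample_batch(run.run_id, (start, end))
        return FetchResult(records=records, spots_retrieved=end - start)
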