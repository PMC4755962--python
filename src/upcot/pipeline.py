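"""End-to-end orchestration: genome bundles + settings -> output directories.

The run proceeds through five pure stages — bundle loading, all-vs-all
homology search per reference (both directions), reciprocal-best-hit
orthology, transcription-unit prediction, and upstream extraction and
clustering — and leaves two directories under the output root:
``tgCoG_protein_sequences`` (one protein FASTA per ortholog group) and
``tu_upstreams`` (one clustered-upstream FASTA per group plus a
manifest).  Every cross-genome iteration is sorted, so a rerun on the
same inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .genome_io import (
    AnnotatedGenome,
    GenomeBundleError,
    link_annotations,
    read_genome_fasta,
    read_protein_fasta,
    read_ptt,
)
from .homology_search import HitTable, ScoringScheme, load_hit_table, search
from .orthology import (
    COG_DIR_NAME,
    build_cogs,
    bdbh_pairs,
    ortholog_counts,
    write_cog_sequences,
)
from .transcription_units import predict_tus
from .upstream_clustering import (
    CLUSTER_DIR_NAME,
    REPRESENTATIVE_MODES,
    WINDOW_MODES,
    cluster_upstreams,
    write_clusters,
)

logger = logging.getLogger(__name__)


class SettingsError(ValueError):
    """A settings file value is unparsable or violates an invariant."""


@dataclass
class Settings:
    """Run parameters, mirroring the legacy settings.txt semantics.

    The E-value cutoff gates hits entering best-hit extraction (default
    1e-3); ``min_orthologs`` is the minimum number of reference genomes
    with a reciprocal best hit for a group to be kept (default 4);
    ``min_up_length``/``max_up_length`` bound extracted upstream lengths
    in bp (defaults 50/350).  The TU gap threshold defaults to
    ``min_up_length`` but is independently settable.
    """

    evalue_cutoff: float = 1e-3
    min_orthologs: int = 4
    min_up_length: int = 50
    max_up_length: int = 350
    tu_gap_threshold: int | None = None
    representative_mode: str = "gene-self"
    window_mode: str = "fixed-window"
    min_members: int = 2

    def __post_init__(self) -> None:
        if self.evalue_cutoff <= 0:
            raise SettingsError("evalue_cutoff: must be > 0")
        if self.min_orthologs < 1:
            raise SettingsError("min_orthologs: must be >= 1")
        if not 0 < self.min_up_length <= self.max_up_length:
            raise SettingsError(
                "min_up_length: require 0 < min_up_length <= max_up_length"
            )
        if self.tu_gap_threshold is None:
            self.tu_gap_threshold = self.min_up_length
        if self.tu_gap_threshold < 0:
            raise SettingsError("tu_gap_threshold: must be >= 0")
        if self.representative_mode not in REPRESENTATIVE_MODES:
            raise SettingsError(
                f"representative_mode: must be one of {REPRESENTATIVE_MODES}"
            )
        if self.window_mode not in WINDOW_MODES:
            raise SettingsError(f"window_mode: must be one of {WINDOW_MODES}")
        if self.min_members < 1:
            raise SettingsError("min_members: must be >= 1")


# legacy settings.txt labels accepted as aliases (normalized form -> field)
_KEY_ALIASES = {
    "e_value": "evalue_cutoff",
    "evalue": "evalue_cutoff",
    "e_value_cutoff": "evalue_cutoff",
    "orthologs_count": "min_orthologs",
    "ortholog_count": "min_orthologs",
    "min_up": "min_up_length",
    "max_up": "max_up_length",
    "min_up_length": "min_up_length",
    "max_up_length": "max_up_length",
}
_IGNORED_KEYS = {"configuration", "gnu_path", "path_of_gnu", "gnu_on_windows_path"}

_FIELD_PARSERS = {
    "evalue_cutoff": float,
    "min_orthologs": int,
    "min_up_length": int,
    "max_up_length": int,
    "tu_gap_threshold": int,
    "min_members": int,
    "representative_mode": str,
    "window_mode": str,
}


def load_settings(path: str | Path) -> Settings:
    """Parse a key=value settings file; defaults fill missing keys.

    Keys are normalized to lowercase snake_case; the legacy labels
    (E value, orthologs count, Max_UP_length, ...) are accepted as
    aliases.  The legacy "Configuration" and GNU-on-Windows path keys
    are recognized and ignored; other unknown keys warn and are skipped.
    """
    values: dict[str, object] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip().rstrip(",")
            if not line:
                continue
            if "=" not in line:
                warnings.warn(
                    f"{path} line {line_no}: no '=' found, line skipped",
                    stacklevel=2,
                )
                continue
            key, _, raw_value = line.partition("=")
            key = key.strip().lower().replace(" ", "_").replace("-", "_")
            key = _KEY_ALIASES.get(key, key)
            if key in _IGNORED_KEYS:
                continue
            if key not in _FIELD_PARSERS:
                warnings.warn(
                    f"{path} line {line_no}: unknown key {key!r} ignored",
                    stacklevel=2,
                )
                continue
            try:
                values[key] = _FIELD_PARSERS[key](raw_value.strip())
            except ValueError as exc:
                raise SettingsError(f"{key}: unparsable value ({exc})") from exc
    return Settings(**values)


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run.

    ``stage_seconds`` carries wall times for operator information only;
    it is excluded from equality so identical inputs compare identical.
    """

    n_target_genes: int
    n_cogs: int
    n_clusters_written: int
    n_below_ortholog_threshold: int
    n_without_orthologs: int
    exclusion_tallies: dict[str, int]
    settings_echo: dict
    stage_seconds: dict[str, float] = field(default_factory=dict, compare=False)

    def to_dict(self, include_timings: bool = True) -> dict:
        d = dataclasses.asdict(self)
        if not include_timings:
            d.pop("stage_seconds")
        return d

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def load_bundle(directory: str | Path) -> AnnotatedGenome:
    """Load and cross-link the one .faa/.fna/.ptt triple in a directory."""
    directory = Path(directory)
    triple = {}
    for ext in (".faa", ".fna", ".ptt"):
        matches = sorted(directory.glob(f"*{ext}"))
        if len(matches) != 1:
            raise GenomeBundleError(
                f"{directory}: expected exactly one *{ext} file, "
                f"found {len(matches)}"
            )
        triple[ext] = matches[0]
    genome = read_genome_fasta(triple[".fna"])
    genes = read_ptt(triple[".ptt"])
    proteins = read_protein_fasta(triple[".faa"])
    return link_annotations(genome, genes, proteins)


def run_pipeline(
    target_dir: str | Path,
    reference_dirs: Sequence[str | Path],
    settings: Settings,
    outdir: str | Path,
    hit_tables_dir: str | Path | None = None,
    scheme: ScoringScheme = ScoringScheme(),
) -> RunReport:
    """Execute the full pipeline and write both output directories.

    When ``hit_tables_dir`` is given, precomputed 12-column tabular hit
    files named ``<query_genome_id>--<subject_genome_id>.tsv`` are
    ingested instead of running the built-in aligner (hits must already
    be E-value-filtered by the external tool, or permissively filtered
    here by the same cutoff).
    """
    if not reference_dirs:
        raise GenomeBundleError("at least one reference genome is required")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    target = load_bundle(target_dir)
    references = sorted(
        (load_bundle(d) for d in reference_dirs), key=lambda g: g.genome_id
    )
    genomes = {g.genome_id: g for g in [target] + references}
    if len(genomes) != len(references) + 1:
        raise GenomeBundleError("duplicate genome ids across bundles")
    timings["load"] = time.perf_counter() - t0
    logger.info("loaded %d genomes, target=%s (%d genes)",
                len(genomes), target.genome_id, len(target.genes))

    t0 = time.perf_counter()
    per_reference: dict[str, set[tuple[str, str]]] = {}
    for ref in references:
        if hit_tables_dir is not None:
            hits_dir = Path(hit_tables_dir)
            fwd = load_hit_table(
                hits_dir / f"{target.genome_id}--{ref.genome_id}.tsv",
                target.genome_id, ref.genome_id,
            )
            rev = load_hit_table(
                hits_dir / f"{ref.genome_id}--{target.genome_id}.tsv",
                ref.genome_id, target.genome_id,
            )
            fwd = _filter_cutoff(fwd, settings.evalue_cutoff)
            rev = _filter_cutoff(rev, settings.evalue_cutoff)
        else:
            fwd = search(
                target.proteome(), ref.proteome(),
                target.genome_id, ref.genome_id,
                scheme, settings.evalue_cutoff,
            )
            rev = search(
                ref.proteome(), target.proteome(),
                ref.genome_id, target.genome_id,
                scheme, settings.evalue_cutoff,
            )
        per_reference[ref.genome_id] = bdbh_pairs(fwd, rev)
        logger.info("%s: %d BDBH pairs", ref.genome_id,
                    len(per_reference[ref.genome_id]))
    timings["homology_bdbh"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    groups = build_cogs(per_reference, settings.min_orthologs)
    counts = ortholog_counts(per_reference)
    n_below = sum(1 for c in counts.values() if c < settings.min_orthologs)
    n_without = len(target.genes) - len(counts)
    write_cog_sequences(groups, genomes, target.genome_id, outdir / COG_DIR_NAME)
    timings["orthology"] = time.perf_counter() - t0
    logger.info("%d ortholog groups at min_orthologs=%d (%d below, %d without)",
                len(groups), settings.min_orthologs, n_below, n_without)

    t0 = time.perf_counter()
    tus_by_genome = {
        gid: predict_tus(genome, settings.tu_gap_threshold)
        for gid, genome in sorted(genomes.items())
    }
    timings["transcription_units"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    clusters = cluster_upstreams(
        groups, genomes, target.genome_id, tus_by_genome,
        min_up=settings.min_up_length,
        max_up=settings.max_up_length,
        window_mode=settings.window_mode,
        representative_mode=settings.representative_mode,
    )
    n_written = write_clusters(clusters, outdir / CLUSTER_DIR_NAME,
                               settings.min_members)
    tallies: dict[str, int] = {}
    for cluster in clusters:
        for reason in cluster.exclusions.values():
            tallies[reason] = tallies.get(reason, 0) + 1
    timings["upstream_clustering"] = time.perf_counter() - t0
    logger.info("%d cluster files written (%s exclusions)",
                n_written, tallies or "no")

    report = RunReport(
        n_target_genes=len(target.genes),
        n_cogs=len(groups),
        n_clusters_written=n_written,
        n_below_ortholog_threshold=n_below,
        n_without_orthologs=n_without,
        exclusion_tallies=dict(sorted(tallies.items())),
        settings_echo=dataclasses.asdict(settings),
        stage_seconds={k: round(v, 4) for k, v in timings.items()},
    )
    report.write_json(outdir / "run_report.json")
    return report


def _filter_cutoff(table: HitTable, cutoff: float) -> HitTable:
    filtered = HitTable(table.query_genome_id, table.subject_genome_id,
                        [h for h in table.hits if h.evalue <= cutoff])
    filtered.sort()
    return filtered
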