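"""Workflow orchestration: define -> transform -> find -> count -> score.

:func:`run_parallel_targeting` is the many-targets workflow (blocking TF
binding sites, CRISPRi/a tiling, ...): targets are transformed with an
arithmetic preset, spacers found per target, off-targets counted
genome-wide with target-set-specific filtering, scores attached, and the
result serialised as a fixed-column TSV.  :func:`run_prime_editing` is the
single-edit PE2/PE3 workflow.  Both record provenance (tool version,
config hash, genome checksum, per-stage counts) and are byte-reproducible:
identical config + inputs give identical TSV output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .genome import Genome, result_columns, write_results
from .intervals import GenomeInterval, apply_preset
from .offtargets import (MatchCounts, aggregate_off, count_genome_matches,
                         count_target_matches, filter_spacers)
from .prime import EditSpec, PrimeDesignParams, design_prime_editing
from .scoring import score_spacers
from .spacers import SpacerHit, find_spacers

logger = logging.getLogger("guideforge")


@dataclass
class RunConfig:
    """Parameters of one design run (paths resolved by the CLI layer)."""

    preset: str | None = "block"
    custom_offsets: tuple[int, int] | None = None
    strand_aware: bool = True
    pam: str = "NGG"
    spacer_len: int = 20
    engine: str = "seeded"
    max_mm: int = 2
    pam_mode: str = "agnostic"
    policy: str = "parallel"
    scorer: str = "ruleset1"
    adapter_cmd: str | None = None
    keep_all: bool = False  # report unfiltered spacers too
    clip: bool = False
    excise_x: int | None = None
    vicinity_offsets: tuple[tuple[int, int], tuple[int, int]] | None = None

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunLog:
    """Provenance and per-stage counts for one run."""

    version: str = __version__
    config_hash: str = ""
    genome_checksum: str = ""
    stages: dict[str, int] = field(default_factory=dict)

    def to_text(self) -> str:
        lines = [
            f"guideforge_version\t{self.version}",
            f"config_hash\t{self.config_hash}",
            f"genome_checksum\t{self.genome_checksum}",
        ]
        lines += [f"stage_{k}\t{v}" for k, v in self.stages.items()]
        return "\n".join(lines) + "\n"


def _transform(targets: Sequence[GenomeInterval], config: RunConfig,
               genome: Genome) -> list[GenomeInterval]:
    if config.custom_offsets is not None:
        from .intervals import extend

        return extend(targets, *config.custom_offsets, config.strand_aware,
                      genome, config.clip)
    if config.preset is None:
        return list(targets)
    if config.preset == "cut_within":
        # The [-16, +5] offsets are spacer-strand-specific: a plus-strand
        # word spans [cut - 16, cut + 6], a minus-strand word [cut - 6,
        # cut + 16].  Searching the symmetric union window and filtering on
        # the cut position (below) realises the per-strand windows exactly.
        from .intervals import extend

        return extend(targets, -16, 16, False, genome, config.clip)
    return apply_preset(targets, config.preset, genome, config.clip,
                        excise_x=config.excise_x,
                        vicinity_offsets=config.vicinity_offsets)


def _cut_inside_parent(spacers: list[SpacerHit],
                       targets: Sequence[GenomeInterval],
                       search_ranges: Sequence[GenomeInterval]
                       ) -> list[SpacerHit]:
    """Keep spacers whose cut position falls inside their original target
    (the cut-within guarantee)."""
    by_range = {id(r): t for t, r in zip(targets, search_ranges)}
    out = []
    for sp in spacers:
        parent = by_range.get(id(sp.target))
        if parent is not None and parent.start <= sp.cut_after <= parent.end:
            out.append(sp)
    return out


def build_result_table(
    spacers: Sequence[SpacerHit],
    counts: dict[str, MatchCounts],
    scores: Sequence,
    max_mm: int,
    score_name: str = "score_rule_set_1",
    extra: dict[str, list] | None = None,
) -> pd.DataFrame:
    rows = []
    for sp, rec in zip(spacers, scores):
        mc = counts.get(sp.spacer_seq, MatchCounts(max_mm))
        row = {
            "target_name": sp.target_name,
            "target_range": str(sp.target) if sp.target else "",
            "spacer_range": str(sp.spacer),
            "spacer_seq": sp.spacer_seq,
            "pam_seq": sp.pam_seq,
            "cut_after": sp.cut_after,
        }
        for m in range(max_mm + 1):
            row[f"T{m}"] = mc.T[m]
        for m in range(max_mm + 1):
            row[f"G{m}"] = mc.G[m]
        off = mc.off
        for m in range(max_mm + 1):
            row[f"off{m}"] = off[m]
        row["off"] = mc.off_total
        row[score_name] = rec.score if rec is not None else None
        rows.append(row)
    cols = result_columns(max_mm, [score_name])
    if extra:
        for k, v in extra.items():
            for row, val in zip(rows, v):
                row[k] = val
            cols.append(k)
    df = pd.DataFrame(rows, columns=cols)
    return df


def run_parallel_targeting(
    targets: Sequence[GenomeInterval],
    genome: Genome,
    config: RunConfig | None = None,
    out_prefix: str | Path | None = None,
) -> tuple[pd.DataFrame, RunLog]:
    """Design spacers for a (possibly large) target set with TSSF.

    Returns the retained-spacer result table plus the run log.  With
    ``config.keep_all`` the table contains every discovered spacer and a
    ``retained`` column instead.
    """
    config = config or RunConfig()
    log = RunLog(config_hash=config.config_hash(),
                 genome_checksum=genome.checksum())
    log.stages["targets_in"] = len(targets)

    search_ranges = _transform(targets, config, genome)
    log.stages["ranges_after_transform"] = len(search_ranges)

    spacers = find_spacers(search_ranges, genome, pam=config.pam,
                           spacer_len=config.spacer_len)
    if config.preset == "cut_within":
        spacers = _cut_inside_parent(spacers, targets, search_ranges)
    log.stages["spacers_found"] = len(spacers)

    if spacers:
        g_counts, matches = count_genome_matches(
            spacers, genome, max_mm=config.max_mm, engine=config.engine,
            pam_mode=config.pam_mode, pam=config.pam)
        t_counts = count_target_matches(matches, search_ranges, config.max_mm)
        counts = aggregate_off(g_counts, t_counts, config.max_mm)
        retained = filter_spacers(spacers, counts, policy=config.policy)
    else:
        counts, retained = {}, []
    log.stages["spacers_retained"] = len(retained)

    report = spacers if config.keep_all else retained
    scores = score_spacers(report, genome, scorer=config.scorer,
                           adapter_cmd=config.adapter_cmd)
    score_name = ("score_rule_set_1" if config.scorer == "ruleset1"
                  else "score_external")
    extra = None
    if config.keep_all:
        kept = {id(sp) for sp in retained}
        extra = {"retained": [int(id(sp) in kept) for sp in report]}
    table = build_result_table(report, counts, scores, config.max_mm,
                               score_name, extra)
    if out_prefix is not None:
        _write_outputs(table, log, out_prefix)
    return table, log


def run_prime_editing(
    edit: EditSpec,
    genome: Genome,
    params: PrimeDesignParams | None = None,
    config: RunConfig | None = None,
    out_prefix: str | Path | None = None,
) -> tuple[pd.DataFrame, RunLog]:
    """PE3 design for one edit; editing and nicking spacers in one table.

    Editing-spacer rows carry the pegRNA 3' extension columns; nicking
    rows carry the nick-to-nick distance and mismatch counts.
    """
    params = params or PrimeDesignParams()
    config = config or RunConfig(policy="unique")
    log = RunLog(config_hash=config.config_hash(),
                 genome_checksum=genome.checksum())
    log.stages["edits_in"] = 1

    designs, nick_counts = design_prime_editing(
        edit, genome, params, max_mm=config.max_mm, engine=config.engine)
    log.stages["editing_spacers"] = len(designs)
    log.stages["nicking_spacers"] = sum(len(d.nicking_spacers)
                                        for d in designs)

    rows: list[SpacerHit] = []
    roles, pbs, rt, ext, dist = [], [], [], [], []
    edit_counts: dict[str, MatchCounts] = {}
    seen_nicks: set[tuple] = set()
    for d in designs:
        rows.append(d.editing_spacer)
        roles.append("editing")
        pbs.append(d.pbs_seq)
        rt.append(d.rt_template_seq)
        ext.append(d.three_prime_extension)
        dist.append(-1)
    if rows:
        edit_counts, edit_matches = count_genome_matches(
            [r.spacer_seq for r in rows], genome, max_mm=config.max_mm,
            engine=config.engine)
        # the declared target for TSSF is the whole admissible design
        # window around the edit, so self-matches are in-target
        reach = params.nrt + 16 + 5 + config.spacer_len
        locus = GenomeInterval(
            edit.chrom, max(1, edit.position - reach),
            min(genome.chrom_length(edit.chrom),
                edit.position + len(edit.ref) - 1 + reach))
        t_counts = count_target_matches(edit_matches, [locus], config.max_mm)
        edit_counts = aggregate_off(edit_counts, t_counts, config.max_mm)
    for d in designs:
        for n, nd in zip(d.nicking_spacers, d.nick_distances):
            key = (str(n.spacer), d.editing_spacer.spacer.start)
            if key in seen_nicks:
                continue
            seen_nicks.add(key)
            rows.append(n)
            roles.append("nicking")
            pbs.append("")
            rt.append("")
            ext.append("")
            dist.append(nd)

    counts = dict(edit_counts)
    for seq, mc in nick_counts.items():
        # a nicking spacer's own locus is its only in-target match
        full = MatchCounts(config.max_mm, G=list(mc.G))
        full.T[0] = min(1, full.G[0])
        counts.setdefault(seq, full)

    scores = score_spacers(rows, genome, scorer=config.scorer,
                           adapter_cmd=config.adapter_cmd)
    score_name = ("score_rule_set_1" if config.scorer == "ruleset1"
                  else "score_external")
    extra = {
        "role": roles,
        "pbs_seq": pbs,
        "rt_template_seq": rt,
        "three_prime_extension": ext,
        "nick_distance": dist,
    }
    table = build_result_table(rows, counts, scores, config.max_mm,
                               score_name, extra)
    if out_prefix is not None:
        _write_outputs(table, log, out_prefix)
    return table, log


def _write_outputs(table: pd.DataFrame, log: RunLog,
                   out_prefix: str | Path) -> None:
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    write_results(table, f"{out_prefix}.tsv")
    Path(f"{out_prefix}.log").write_text(log.to_text())
    logger.info("wrote %s.tsv (%d rows)", out_prefix, len(table))
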