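"""On-target efficiency scoring.

Scores annotate spacers, never remove them.  Two scorers are provided:

* :func:`score_rule_set_1` - the classic logistic regression over a 30-nt
  context (4 nt upstream + 20-nt protospacer + 3-nt PAM + 3 nt
  downstream): intercept + position-specific mononucleotide and
  dinucleotide weights + a GC-count penalty, pushed through a logistic.
  The weight table is vendored as a TSV data file whose sha256 is checked
  at load time.

* :func:`score_external` - a line-oriented adapter for any external scorer
  (one 30-mer context per input line, one score per output line), so that
  trained models distributed as separate programs can be plugged in
  without being re-implemented here.  A missing or failing adapter yields
  missing scores, never an aborted design run.
"""

from __future__ import annotations

import hashlib
import logging
import math
import subprocess
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

from .genome import Genome
from .intervals import MINUS, GenomeInterval
from .spacers import SpacerHit

logger = logging.getLogger("guideforge")

CONTEXT_LEN = 30
_UPSTREAM = 4  # bases of context 5' of the protospacer
_DOWNSTREAM = 3  # bases of context 3' of the PAM

#: sha256 of the vendored Rule Set 1 weight table.
RULE_SET_1_SHA256 = "64bbc3a9771d00c3692d5c69d73f39a8b82be007e4203ae7b05f5b2931710782"


@dataclass(frozen=True)
class ScoringContext:
    """30-nt window read 5'->3' on the spacer strand; positions 25-27
    (1-based) hold the PAM."""

    context30: str
    spacer_id: str = ""

    def __post_init__(self) -> None:
        if len(self.context30) != CONTEXT_LEN:
            raise ValueError(
                f"context must be {CONTEXT_LEN} nt, got {len(self.context30)}"
            )
        if set(self.context30) - set("ACGT"):
            raise ValueError(f"context has non-ACGT bases: {self.context30}")


@dataclass(frozen=True)
class ScoreRecord:
    spacer_id: str
    scorer: str
    score: float | None  # None = unscorable / adapter missing


def build_context(spacer: SpacerHit, genome: Genome) -> ScoringContext | None:
    """Strand-aware 30-mer extraction; ``None`` flags an unscorable spacer
    (window truncated by a chromosome end or containing ambiguous bases),
    which is kept in the result set, just without a score."""
    iv = spacer.spacer
    if iv.strand == MINUS:
        start, end = iv.start - (len(spacer.pam_seq) + _DOWNSTREAM), iv.end + _UPSTREAM
    else:
        start, end = iv.start - _UPSTREAM, iv.end + len(spacer.pam_seq) + _DOWNSTREAM
    if start < 1 or end > genome.chrom_length(iv.chrom):
        return None
    seq = genome.fetch(GenomeInterval(iv.chrom, start, end, iv.strand))
    if set(seq) - set("ACGT"):
        return None
    return ScoringContext(seq, spacer_id=str(iv))


def _load_weights() -> tuple[float, float, float, dict[tuple[str, int], float]]:
    data = (resources.files("guideforge") / "data" / "rule_set_1_weights.tsv")
    raw = data.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != RULE_SET_1_SHA256:
        raise RuntimeError(
            f"rule_set_1_weights.tsv checksum mismatch: {digest}"
        )
    intercept = gc_low = gc_high = 0.0
    table: dict[tuple[str, int], float] = {}
    for line in raw.decode().splitlines()[1:]:
        feature, pos_s, weight_s = line.split("\t")
        pos, weight = int(pos_s), float(weight_s)
        if feature == "Intercept":
            intercept = weight
        elif feature == "gc_low":
            gc_low = weight
        elif feature == "gc_high":
            gc_high = weight
        else:
            table[(feature, pos)] = weight
    return intercept, gc_low, gc_high, table


_WEIGHTS: tuple | None = None


def score_rule_set_1(ctx: ScoringContext) -> ScoreRecord:
    """Logistic position-weight score in (0, 1); deterministic and pure."""
    global _WEIGHTS
    if _WEIGHTS is None:
        _WEIGHTS = _load_weights()
    intercept, gc_low, gc_high, table = _WEIGHTS
    seq = ctx.context30
    score = intercept
    gc = seq[_UPSTREAM : _UPSTREAM + 20].count("G") + \
        seq[_UPSTREAM : _UPSTREAM + 20].count("C")
    if gc < 10:
        score += gc_low * (10 - gc)
    elif gc > 10:
        score += gc_high * (gc - 10)
    for pos in range(CONTEXT_LEN):
        score += table.get((seq[pos], pos), 0.0)
        if pos < CONTEXT_LEN - 1:
            score += table.get((seq[pos : pos + 2], pos), 0.0)
    return ScoreRecord(ctx.spacer_id, "rule_set_1",
                       1.0 / (1.0 + math.exp(-score)))


def score_external(
    contexts: Sequence[ScoringContext],
    adapter_cmd: str | None,
    scorer_name: str = "external",
    timeout: float = 600.0,
) -> list[ScoreRecord]:
    """Batch contexts through an external scoring command.

    The adapter reads one 30-mer per line on stdin and writes one numeric
    score per line on stdout.  No adapter, a failing adapter or malformed
    output all degrade to missing scores with a warning.
    """
    missing = [ScoreRecord(c.spacer_id, scorer_name, None) for c in contexts]
    if not contexts:
        return []
    if not adapter_cmd:
        return missing
    payload = "\n".join(c.context30 for c in contexts) + "\n"
    try:
        proc = subprocess.run(
            adapter_cmd, input=payload, capture_output=True, text=True,
            shell=True, timeout=timeout,
        )
    except (OSError, subprocess.TimeoutExpired) as exc:
        logger.warning("external scorer failed: %s", exc)
        return missing
    if proc.returncode != 0:
        logger.warning("external scorer exited %d: %s", proc.returncode,
                       proc.stderr.strip()[:500])
        return missing
    lines = proc.stdout.split()
    if len(lines) != len(contexts):
        logger.warning(
            "external scorer returned %d values for %d contexts; "
            "scores reported as missing", len(lines), len(contexts))
        return missing
    out = []
    for c, line in zip(contexts, lines):
        try:
            out.append(ScoreRecord(c.spacer_id, scorer_name, float(line)))
        except ValueError:
            logger.warning("malformed score %r from external scorer", line)
            out.append(ScoreRecord(c.spacer_id, scorer_name, None))
    return out


def score_spacers(
    spacers: Sequence[SpacerHit],
    genome: Genome,
    scorer: str = "ruleset1",
    adapter_cmd: str | None = None,
) -> list[ScoreRecord]:
    """Score a spacer list without altering it; unscorable -> None."""
    contexts = [build_context(sp, genome) for sp in spacers]
    if scorer == "ruleset1":
        return [
            score_rule_set_1(c) if c is not None
            else ScoreRecord(str(sp.spacer), "rule_set_1", None)
            for sp, c in zip(spacers, contexts)
        ]
    if scorer == "external":
        valid = [c for c in contexts if c is not None]
        scored = {r.spacer_id: r for r in
                  score_external(valid, adapter_cmd)}
        return [
            scored.get(c.spacer_id, ScoreRecord(str(sp.spacer), "external", None))
            if c is not None else ScoreRecord(str(sp.spacer), "external", None)
            for sp, c in zip(spacers, contexts)
        ]
    raise ValueError(f"unknown scorer {scorer!r}")
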