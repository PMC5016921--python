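"""Judgement-file I/O and the end-to-end study pipeline.

Judgement CSVs have one row per respondent x comparison:

    respondent_id,source,parent_id,left_id,right_id,value

where ``value`` is an integer 1..9 or a fraction ``1/2`` .. ``1/9`` and
``source`` is ``individual`` or ``group``.  The dialect is spreadsheet-
friendly on purpose: questionnaire data for studies like this are typically
transcribed by hand.

:func:`run_study` ties the stages together — read or simulate judgements,
prioritize, screen on consistency, aggregate by every requested method and
compare sources — and writes a reproducible report bundle.  Every number in
the bundle is re-derivable by calling the underlying modules directly.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import compare as cmp
from .aggregate import METHODS, aggregate, rank_table
from .core import (IncompleteJudgementError, JudgementSet, PriorityResult,
                   ScaleError, format_scale_value, parse_scale_value,
                   prioritize)
from .hierarchy import ComparisonSlot, Hierarchy, enumerate_slots
from .screen import ScreenPolicy, sample_size_curve, screen
from .simulate import SimulationConfig, simulate_cohort

__all__ = ["JudgementParseError", "read_judgements", "write_judgements",
           "RunConfig", "run_study"]

logger = logging.getLogger("ahpkit")

_COLUMNS = ["respondent_id", "source", "parent_id", "left_id", "right_id",
            "value"]


class JudgementParseError(ValueError):
    """A judgement CSV violates the documented dialect; messages carry the
    offending line number."""


def write_judgements(sets: Sequence[JudgementSet], path) -> None:
    """Write judgement sets to CSV in the documented dialect."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for js in sets:
            for slot, value in js.judgements.items():
                writer.writerow([js.respondent_id, js.source, slot.parent_id,
                                 slot.left_id, slot.right_id,
                                 format_scale_value(value)])


def read_judgements(path, h: Hierarchy) -> list[JudgementSet]:
    """Read one or many respondents' judgements from a CSV file.

    Values are parsed exactly (integers and ``1/k`` fractions); slots
    recorded in the flipped orientation are normalized via the reciprocal
    convention.  Unknown node ids, off-scale values, duplicate slots and
    incomplete respondents each raise a line-numbered
    :class:`JudgementParseError`.
    """
    slots = enumerate_slots(h)
    slot_set = set(slots)
    flipped = {ComparisonSlot(s.parent_id, s.right_id, s.left_id): s
               for s in slots}
    sets: dict[str, JudgementSet] = {}
    last_line: dict[str, int] = {}

    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or \
                [c.strip() for c in reader.fieldnames] != _COLUMNS:
            raise JudgementParseError(
                f"{path}: header must be exactly {','.join(_COLUMNS)}")
        for lineno, row in enumerate(reader, start=2):
            rid = (row.get("respondent_id") or "").strip()
            if not rid:
                raise JudgementParseError(f"{path}:{lineno}: empty respondent_id")
            source = (row.get("source") or "").strip()
            slot = ComparisonSlot((row.get("parent_id") or "").strip(),
                                  (row.get("left_id") or "").strip(),
                                  (row.get("right_id") or "").strip())
            try:
                value = parse_scale_value(row.get("value") or "")
            except ScaleError as exc:
                raise JudgementParseError(f"{path}:{lineno}: {exc}") from exc
            if slot in slot_set:
                canonical, canonical_value = slot, value
            elif slot in flipped:
                canonical, canonical_value = flipped[slot], 1 / value
            else:
                raise JudgementParseError(
                    f"{path}:{lineno}: {slot.left_id!r} vs {slot.right_id!r} "
                    f"under {slot.parent_id!r} is not a comparison of this "
                    "hierarchy")
            js = sets.get(rid)
            if js is None:
                try:
                    js = JudgementSet(respondent_id=rid, source=source)
                except ValueError as exc:
                    raise JudgementParseError(f"{path}:{lineno}: {exc}") from exc
                sets[rid] = js
            elif js.source != source:
                raise JudgementParseError(
                    f"{path}:{lineno}: respondent {rid!r} changes source "
                    f"from {js.source!r} to {source!r}")
            if canonical in js.judgements:
                raise JudgementParseError(
                    f"{path}:{lineno}: duplicate judgement for respondent "
                    f"{rid!r}, slot {canonical}")
            js.judgements[canonical] = canonical_value
            last_line[rid] = lineno

    for rid, js in sets.items():
        missing = [s for s in slots if s not in js.judgements]
        if missing:
            m = missing[0]
            raise JudgementParseError(
                f"{path}:{last_line[rid]}: respondent {rid!r} is incomplete: "
                f"missing {m.left_id!r} vs {m.right_id!r} under "
                f"{m.parent_id!r} ({len(missing)} slot(s) in total)")
    return list(sets.values())


@dataclass
class RunConfig:
    """Configuration of an end-to-end study run.

    Either point ``individual_csv``/``group_csv`` at judgement files or set
    ``simulate`` to generate a synthetic cohort; outputs land in ``out_dir``.
    """

    hierarchy: Hierarchy
    out_dir: Path
    individual_csv: Path | None = None
    group_csv: Path | None = None
    simulate: SimulationConfig | None = None
    policy: ScreenPolicy = field(default_factory=ScreenPolicy)
    methods: tuple[str, ...] = METHODS
    curve_thresholds: tuple[float, ...] = (0.05, 0.1, 0.15, 0.2, 0.25, 0.3)


def _priorities_frame(results: Sequence[PriorityResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"respondent_id": r.respondent_id, "source": r.source,
               **{f"w_{leaf}": w for leaf, w in r.global_weights.items()},
               **{f"worst_cr_level{lv}": cr
                  for lv, cr in sorted(r.worst_cr_by_level.items())}}
        rows.append(row)
    return pd.DataFrame(rows)


def run_study(cfg: RunConfig) -> dict:
    """Run the full pipeline and write the report bundle to ``cfg.out_dir``.

    Writes per-respondent priorities, the screening outcome, the sample-size
    curve, per-method aggregate weight/rank tables, individual-vs-group
    comparison tables and a machine-readable ``summary.json``.  Returns the
    summary dict.  Outputs are a pure function of (inputs, seed, config).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.simulate is not None:
        individuals, groups, latents = simulate_cohort(cfg.simulate)
        write_judgements(individuals, out / "individual_judgements.csv")
        write_judgements(groups, out / "group_judgements.csv")
        with open(out / "latent_weights.json", "w", encoding="utf-8") as fh:
            json.dump(latents, fh, indent=2, sort_keys=True)
        logger.info("simulated %d individual and %d group judgement sets",
                    len(individuals), len(groups))
    else:
        individuals = (read_judgements(cfg.individual_csv, cfg.hierarchy)
                       if cfg.individual_csv else [])
        groups = (read_judgements(cfg.group_csv, cfg.hierarchy)
                  if cfg.group_csv else [])
        logger.info("read %d individual and %d group judgement sets",
                    len(individuals), len(groups))
    if not individuals:
        raise ValueError("no individual judgement sets to analyze")

    all_sets = individuals + groups
    results = [prioritize(js, cfg.hierarchy) for js in all_sets]
    _priorities_frame(results).to_csv(out / "priorities.tsv", sep="\t",
                                      index=False, float_format="%.6f")
    logger.info("prioritized %d respondents", len(results))

    outcome = screen(results, cfg.policy)
    with open(out / "screen.tsv", "w", encoding="utf-8") as fh:
        fh.write("respondent_id\tincluded\toffending_parent\tcr\n")
        for rid in outcome.included:
            fh.write(f"{rid}\tyes\t\t\n")
        for exc in outcome.excluded:
            fh.write(f"{exc.respondent_id}\tno\t{exc.parent_id}\t{exc.cr:.4f}\n")
    logger.info("screen (%s): %d included, %d excluded", cfg.policy.label,
                len(outcome.included), len(outcome.excluded))

    curve = sample_size_curve(results, list(cfg.curve_thresholds),
                              [{2}, {2, 3}])
    curve.to_csv(out / "sample_size_curve.tsv", sep="\t")

    included = [r for r in results if r.respondent_id in set(outcome.included)]
    ind_included = [r for r in included if r.source == "individual"]
    grp_included = [r for r in included if r.source == "group"]

    reports = [aggregate(included, m) for m in cfg.methods]
    for rep in reports:
        frame = pd.DataFrame({"weight": rep.global_weights,
                              "rank": rep.ranks})
        frame.index.name = "leaf"
        frame.to_csv(out / f"aggregate_{rep.method}.tsv", sep="\t",
                     float_format="%.6f")
    ranks, differing = rank_table(reports)
    ranks.index.name = "leaf"
    ranks.to_csv(out / "rank_comparison.tsv", sep="\t")
    logger.info("aggregated %d included respondents by %s; %d leaves differ "
                "in rank across methods", len(included),
                "/".join(cfg.methods), len(differing))

    summary: dict = {
        "n_individual": len(individuals),
        "n_group": len(groups),
        "screen_policy": cfg.policy.label,
        "n_included": len(outcome.included),
        "n_excluded": len(outcome.excluded),
        "included_ids": sorted(outcome.included),
        "rank_differences_across_methods": differing,
        "aggregate_ranks": {rep.method: {leaf: int(rank) for leaf, rank
                                         in rep.ranks.items()}
                            for rep in reports},
    }

    if ind_included and grp_included:
        ind_rep = aggregate(ind_included, "arithmetic")
        grp_rep = aggregate(grp_included, "arithmetic")
        node_cmp = cmp.local_rank_comparison(ind_rep, grp_rep)
        with open(out / "local_rank_comparison.tsv", "w", encoding="utf-8") as fh:
            fh.write("parent_id\tindividual_order\tgroup_order\tidentical\n")
            for nc in node_cmp:
                fh.write(f"{nc.parent_id}\t{'>'.join(nc.order_a)}\t"
                         f"{'>'.join(nc.order_b)}\t"
                         f"{'yes' if nc.identical else 'no'}\n")
        ind_sets = [s for s in all_sets if s.source == "individual"]
        grp_sets = [s for s in all_sets if s.source == "group"]
        dist_rows = []
        for label, ss in (("individual", ind_sets), ("group", grp_sets)):
            dist = cmp.answer_distribution(ss, source=label)
            for k, p in enumerate(dist.cumulative, start=1):
                dist_rows.append({"source": label, "magnitude": k,
                                  "cumulative": p})
        pd.DataFrame(dist_rows).to_csv(out / "answer_distribution.tsv",
                                       sep="\t", index=False,
                                       float_format="%.6f")
        t, p = cmp.response_behavior_test(ind_sets, grp_sets)
        summary["local_ranks_identical"] = sum(nc.identical for nc in node_cmp)
        summary["local_ranks_total"] = len(node_cmp)
        summary["response_behavior_t"] = t
        summary["response_behavior_p"] = p
        logger.info("individual-vs-group: %d/%d nodes rank-identical, "
                    "t = %.3f, p = %.4g", summary["local_ranks_identical"],
                    len(node_cmp), t, p)

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("report bundle written to %s", out)
    return summary
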