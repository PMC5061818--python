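"""End-to-end pipeline orchestration and summary arithmetic.

The run configuration names the samples (one C parent, one or two
A-parent/hybrid trios), points at the input (a synthetic simulation, a
counts TSV, or per-library SAM files plus annotation) and fixes alpha, the
percentage rounding and the output directory.  ``run_pipeline`` then emits
per-gene TSVs for every stage plus one JSON summary whose every percentage
is recomputed from its stored counts.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bias as bias_mod
from . import classify as classify_mod
from . import iofilter
from .containers import CountTable, sign_symbol
from .diffexpr import differential_contrast, mpv_pseudo_sample
from .simulate import SimulationConfig, generate_dataset

__all__ = ["percent", "mean_integer", "RunConfig", "run_pipeline",
           "render_text"]

SCHEMA_VERSION = 1


def percent(numerator, denominator, decimals: int = 1) -> float:
    """``100 * numerator / denominator`` rounded half-up to ``decimals``."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    ratio = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(ratio.quantize(quantum, rounding=ROUND_HALF_UP))


def mean_integer(values) -> int:
    """Integer part (floor) of the arithmetic mean of non-negative integers."""
    values = list(values)
    if not values:
        raise ValueError("mean of an empty list")
    if any(v < 0 for v in values):
        raise ValueError("values must be non-negative")
    return int(math.floor(sum(values) / len(values)))


@dataclass
class RunConfig:
    """Validated pipeline configuration (see module docstring)."""

    trios: list            # [{"a": "AA1", "c": "CC", "h": "AC1"}, ...]
    mode: str = "synthetic"            # synthetic | counts | sam
    alpha: float = 0.05
    rounding: int = 1
    seed: int = 0
    outdir: str = "polyeld_out"
    denominator: str = "union"         # union | both
    universe: str = "either"           # homoeolog-pair expression filter
    min_mapq: int = 1
    simulation: dict = field(default_factory=dict)
    counts: str | None = None
    annotation: str | None = None
    pairs: str | None = None
    sam: dict = field(default_factory=dict)   # sample -> [replicate SAMs]

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.mode not in ("synthetic", "counts", "sam"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.trios:
            raise ValueError("at least one A-parent/hybrid trio is required")
        c_parents = {t["c"] for t in self.trios}
        if len(c_parents) != 1:
            raise ValueError("exactly one C parent per run")
        if self.denominator not in ("union", "both"):
            raise ValueError("denominator must be 'union' or 'both'")
        if self.mode == "counts" and not self.counts:
            raise ValueError("counts mode needs a counts path")
        if self.mode == "sam" and (not self.sam or not self.annotation):
            raise ValueError("sam mode needs SAM files and an annotation")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _load_inputs(config: RunConfig):
    genes, truth = None, None
    if config.mode == "synthetic":
        sim = dict(config.simulation)
        sim.setdefault("seed", config.seed)
        dataset = generate_dataset(SimulationConfig(**sim))
        counts, genes, truth = dataset.counts, dataset.genes, dataset.truth
        logs = {}
    elif config.mode == "counts":
        counts = iofilter.read_counts(config.counts)
        if config.annotation:
            genes = iofilter.read_annotation(config.annotation,
                                             pairs_path=config.pairs)
        logs = {}
    else:
        genes = iofilter.read_annotation(config.annotation,
                                         pairs_path=config.pairs)
        paths = {}
        for sample, reps in config.sam.items():
            for i, path in enumerate(reps, start=1):
                paths[(sample, i)] = path
        counts, logs = iofilter.filter_and_count_many(
            paths, genes, min_mapq=config.min_mapq)
    return counts, genes, truth, logs


def _de_entry(counts: CountTable, x: str, y: str, alpha: float,
              denominator: str, decimals: int) -> dict:
    calls = differential_contrast(counts, (x, y), alpha=alpha)
    up = int((calls["sign"] == 1).sum())
    down = int((calls["sign"] == -1).sum())
    if denominator == "union":
        denom = len(calls)
    else:
        denom = int(counts.expressed(x).sum() + counts.expressed(y).sum())
    return {
        "contrast": f"{x}:{y}",
        "n_tested": len(calls),
        "de_total": up + down,
        "up_in_first": up,
        "down_in_first": down,
        "denominator": denom,
        "de_percent": percent(up + down, denom, decimals),
        "up_percent": percent(up, denom, decimals),
        "down_percent": percent(down, denom, decimals),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write per-gene TSVs plus the summary report.

    Deterministic given the configuration and inputs.  Returns the report
    dict (also written as ``report.json`` and a text rendering)."""
    t0 = time.perf_counter()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts, genes, truth, filter_logs = _load_inputs(config)
    iofilter.write_counts(counts, outdir / "counts.tsv")
    if truth is not None:
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)

    report = {
        "schema_version": SCHEMA_VERSION,
        "alpha": config.alpha,
        "mode": config.mode,
        "seed": config.seed,
        "n_genes": counts.n_genes,
        "library_sizes": {s: counts.library_size(s) for s in counts.samples},
        "filter_logs": filter_logs,
        "trios": {},
    }
    timings = {}

    assignments = {}
    pair_calls = {}
    for trio in config.trios:
        a, c, h = trio["a"], trio["c"], trio["h"]
        t_stage = time.perf_counter()
        de = {
            "parents": _de_entry(counts, a, c, config.alpha,
                                 config.denominator, config.rounding),
            "hybrid_vs_a": _de_entry(counts, h, a, config.alpha,
                                     config.denominator, config.rounding),
            "hybrid_vs_c": _de_entry(counts, h, c, config.alpha,
                                     config.denominator, config.rounding),
        }
        frame, summary = classify_mod.classify_all(
            counts, a, c, h, alpha=config.alpha)
        assignments[h] = frame
        out_frame = frame.copy()
        for col in ("s_pc", "s_ha", "s_hc", "s_h_mpv"):
            out_frame[col] = [sign_symbol(v) for v in out_frame[col]]
        out_frame.to_csv(outdir / f"patterns_{h}.tsv", sep="\t")
        entry = {
            "samples": {"a": a, "c": c, "h": h},
            "differential": de,
            "classification": summary.as_dict(),
            "additive_percent": percent(summary.additive,
                                        summary.n_classified,
                                        config.rounding),
            "non_additive_percent": percent(
                summary.non_additive_up + summary.non_additive_down,
                summary.n_classified, config.rounding),
        }
        if genes is not None and any(g.partner_id for g in genes):
            calls = bias_mod.classify_pairs(
                counts, genes, a, c, h, alpha=config.alpha,
                universe=config.universe)
            pair_calls[h] = calls
            out_calls = calls.copy()
            for col in ("parent_sign", "hybrid_sign"):
                out_calls[col] = [sign_symbol(v) for v in out_calls[col]]
            out_calls.to_csv(outdir / f"bias_{h}.tsv", sep="\t")
        report["trios"][h] = entry
        timings[h] = round(time.perf_counter() - t_stage, 3)

    hybrids = [t["h"] for t in config.trios]
    for h in hybrids:
        if h in pair_calls:
            other = next((pair_calls[o] for o in hybrids
                          if o != h and o in pair_calls), None)
            report["trios"][h]["bias"] = bias_mod.summarize_bias(
                pair_calls[h], other)
    if len(hybrids) >= 2 and all(h in assignments for h in hybrids[:2]):
        cross = classify_mod.cross_compare(assignments[hybrids[0]],
                                           assignments[hybrids[1]])
        report["cross_hybrid"] = {
            k: v for k, v in cross.items() if not isinstance(k, str) or
            not k.endswith("contingency")
        }
        report["cross_hybrid"]["additive_contingency"] = \
            cross["additive_contingency"].to_dict()
        report["cross_hybrid"]["eld_contingency"] = \
            cross["eld_contingency"].to_dict()
        report["cross_hybrid"]["shared_additive_percent"] = percent(
            cross["shared_additive"], cross["n_shared"], config.rounding)

    # timings go to a side log so report.json is byte-deterministic
    timings["total"] = round(time.perf_counter() - t0, 3)
    with open(outdir / "timings.json", "w") as fh:
        json.dump(timings, fh, indent=2, sort_keys=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    with open(outdir / "report.txt", "w") as fh:
        fh.write(render_text(report))
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict())
    return obj


def render_text(report: dict) -> str:
    """Human-readable rendering of the summary report."""
    lines = [f"polyeld report (alpha={report['alpha']}, "
             f"mode={report['mode']}, genes={report['n_genes']})", ""]
    for h in sorted(report["trios"]):
        entry = report["trios"][h]
        s = entry["classification"]
        lines.append(f"== trio {entry['samples']['a']} / "
                     f"{entry['samples']['c']} / {h} ==")
        for key in ("parents", "hybrid_vs_a", "hybrid_vs_c"):
            de = entry["differential"][key]
            lines.append(
                f"  {key:12s} {de['contrast']:10s} DE {de['de_total']:>7d} "
                f"({de['de_percent']}%)  up {de['up_in_first']} "
                f"down {de['down_in_first']}"
            )
        lines.append(
            f"  classified {s['n_classified']}: additive {s['additive']} "
            f"({entry['additive_percent']}%), non-additive up "
            f"{s['non_additive_up']} / down {s['non_additive_down']}"
        )
        lines.append(
            f"  dominance A {s['a_dominance']} vs C {s['c_dominance']} "
            f"(balance p={s['dominance_balance_p']:.3g}); transgressive up "
            f"{s['transgressive_up']} vs down {s['transgressive_down']} "
            f"(p={s['transgressive_balance_p']:.3g})"
        )
        if "bias" in entry:
            b = entry["bias"]
            lines.append(
                f"  homoeolog pairs {b['total_pairs']}: overall A-bias "
                f"{b['overall_A_bias']} ({b['overall_A_bias_percent']}%), "
                f"C-bias {b['overall_C_bias']} "
                f"({b['overall_C_bias_percent']}%), balance "
                f"p={b['balance_p']:.3g}"
            )
            for cat in bias_mod.CATEGORY_ORDER:
                lines.append(
                    f"    {cat:20s} {b['category_counts'][cat]:>7d} "
                    f"({b['category_percent'][cat]}%)"
                )
        lines.append("")
    if "cross_hybrid" in report:
        x = report["cross_hybrid"]
        lines.append(
            f"cross-hybrid: shared {x['n_shared']}, same additive state "
            f"{x['same']}, changed {x['changed']}, opposite {x['opposite']}; "
            f"shared additive {x['shared_additive']} "
            f"({x['shared_additive_percent']}%)"
        )
    return "\n".join(lines) + "\n"
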