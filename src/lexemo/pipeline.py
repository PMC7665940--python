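"""End-to-end orchestration: tag → align → metrics → compare → report.

A run takes one or more dictionary versions (or pre-tagged token tables),
a corpus and a token-level reference annotation, and produces a single
machine-readable report containing per-version per-category diagnostic
metrics with confidence intervals, per-participant percentage summaries,
Pearson correlation matrices, and Bonferroni-corrected pairwise
two-proportion comparisons between versions.  Reports are deterministic
given the configuration and seed: running twice yields identical bytes.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import io as lio
from .errors import ConfigError, LexemoError, StageFailure
from .lexicon import Document, Lexicon, TaggedCorpus, Token, read_lexicon, tag_corpus
from .metrics import (
    ComparisonResult,
    bonferroni,
    confusion,
    f_score,
    npv,
    pearson_correlation,
    ppv,
    sensitivity,
    specificity,
    two_proportion_test,
)
from .reference import AlignedCorpus, align

__all__ = ["RunConfig", "RunReport", "compare_versions", "run_validation"]

logger = logging.getLogger("lexemo.pipeline")

_CATS: tuple[str, ...] = ("affect", "posemo", "negemo", "anx", "anger", "sad")
_DIAG_METRICS = ("sensitivity", "specificity", "ppv", "npv")


@dataclass
class RunConfig:
    """Configuration of one validation run.

    ``lexicons`` maps a version tag to a dictionary file to run through
    the lexicon engine; ``predictions`` maps a version tag to a
    pre-tagged token TSV (as written by ``lexemo tag``).  At least one
    of the two must be nonempty.
    """

    corpus: str | Path
    reference: str | Path
    lexicons: dict[str, str | Path] = field(default_factory=dict)
    predictions: dict[str, str | Path] = field(default_factory=dict)
    ci_method: str = "wilson"
    alpha: float = 0.05
    family_diagnostic: int = 24
    family_f: int = 6
    seed: int = 0
    out_dir: str | Path | None = None

    def validate(self) -> None:
        if not self.lexicons and not self.predictions:
            raise ConfigError("configure at least one lexicon or "
                              "prediction table")
        overlap = set(self.lexicons) & set(self.predictions)
        if overlap:
            raise ConfigError(
                f"version tags {sorted(overlap)} appear as both lexicon "
                "and prediction inputs"
            )
        if self.ci_method not in ("wilson", "wald"):
            raise ConfigError(f"unknown CI method {self.ci_method!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError("alpha must lie in (0, 1)")
        if self.family_diagnostic < 1 or self.family_f < 1:
            raise ConfigError("Bonferroni family sizes must be ≥ 1")
        for name, paths in (("lexicon", self.lexicons),
                            ("prediction", self.predictions)):
            for tag, p in paths.items():
                if not Path(p).exists():
                    raise ConfigError(
                        f"{name} path for version {tag!r} does not "
                        f"exist: {p}"
                    )
        for name, p in (("corpus", self.corpus),
                        ("reference", self.reference)):
            if not Path(p).exists():
                raise ConfigError(f"{name} path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def canonical(self) -> dict:
        return {
            "corpus": str(self.corpus),
            "reference": str(self.reference),
            "lexicons": {k: str(v) for k, v in sorted(self.lexicons.items())},
            "predictions": {
                k: str(v) for k, v in sorted(self.predictions.items())
            },
            "ci_method": self.ci_method,
            "alpha": self.alpha,
            "family_diagnostic": self.family_diagnostic,
            "family_f": self.family_f,
            "seed": self.seed,
        }

    def hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode("utf-8")
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """Machine-readable result of one validation run."""

    data: dict

    def to_json(self) -> str:
        return json.dumps(self.data, sort_keys=True, indent=2) + "\n"

    @property
    def versions(self) -> list[str]:
        return self.data["provenance"]["versions"]

    def metric(self, version: str, category: str, name: str) -> dict:
        return self.data["metrics"][version][category][name]

    def render_tables(self) -> dict[str, pd.DataFrame]:
        """Human-readable tables with pairwise significance letters."""
        data = self.data
        versions = self.versions
        pairs = list(itertools.combinations(versions, 2))
        letters = {pair: chr(ord("b") + i) for i, pair in enumerate(pairs)}

        def letter_suffix(metric: str, cat: str, version: str) -> str:
            out = ""
            for pair in pairs:
                if version not in pair:
                    continue
                cell = data["comparisons"][metric][cat].get(
                    f"{pair[0]}_vs_{pair[1]}"
                )
                if cell and cell["significant"]:
                    out += letters[pair]
            return out

        tables: dict[str, pd.DataFrame] = {}
        pct_rows = []
        for cat in _CATS:
            row: dict[str, object] = {"category": cat}
            for col in versions + ["human"]:
                cell = data["percentages"][col][cat]
                row[col] = f"{cell['mean']:.1f} ({cell['sd']:.3f})"
            pct_rows.append(row)
        tables["percentages"] = pd.DataFrame(pct_rows)

        for metric in _DIAG_METRICS:
            rows = []
            for cat in _CATS:
                row = {"category": cat}
                for v in versions:
                    m = data["metrics"][v][cat][metric]
                    row[v] = (
                        f"{m['value']:.3f}{letter_suffix(metric, cat, v)} "
                        f"({m['ci_low']:.3f}-{m['ci_high']:.3f})"
                    )
                rows.append(row)
            tables[metric] = pd.DataFrame(rows)

        rows = []
        for cat in _CATS:
            row = {"category": cat}
            for v in versions:
                m = data["metrics"][v][cat]["f_score"]
                row[v] = f"{m['value']:.3f}"
            for pair in pairs:
                cell = data["comparisons"]["f_score"][cat].get(
                    f"{pair[0]}_vs_{pair[1]}"
                )
                key = f"p {pair[0]} vs {pair[1]}"
                if cell is None:
                    row[key] = "-"
                else:
                    row[key] = (
                        f"{cell['p_value']:.4f}"
                        + ("*" if cell["significant"] else "")
                    )
            rows.append(row)
        tables["f_score"] = pd.DataFrame(rows)

        for name, matrix in data["correlations"].items():
            tables[f"correlation_{name}"] = pd.DataFrame(matrix).T
        return tables


@contextmanager
def _stage(name: str):
    t0 = time.perf_counter()
    try:
        yield
    except LexemoError as exc:
        raise StageFailure(name, exc) from exc
    except (OSError, ValueError, KeyError) as exc:
        raise StageFailure(name, exc) from exc
    finally:
        logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)


def _tagged_from_tsv(tag: str, path: str | Path) -> TaggedCorpus:
    """Rebuild a TaggedCorpus from a pre-tagged token TSV."""
    table = pd.read_csv(Path(path), sep="\t", dtype=str,
                        keep_default_na=False)
    required = {"participant_id", "position", "surface", "norm",
                "categories"}
    if not required.issubset(table.columns):
        raise ConfigError(
            f"tagged TSV needs columns {sorted(required)}"
        )
    docs: list[Document] = []
    tags: list[tuple[frozenset[str], ...]] = []
    for pid, group in table.groupby("participant_id", sort=True):
        group = group.assign(position=group["position"].astype(int))
        group = group.sort_values("position")
        tokens = tuple(
            Token(row.surface, row.norm, row.position)
            for row in group.itertuples(index=False)
        )
        docs.append(Document(str(pid), tokens))
        tags.append(
            tuple(
                frozenset(c for c in row.categories.split(",") if c)
                for row in group.itertuples(index=False)
            )
        )
    return TaggedCorpus(tag, tuple(docs), tuple(tags))


def _percentage_summary(aligned: AlignedCorpus, side: str) -> dict:
    """Per-participant category percentages, averaged unweighted across
    participants (mean and SD)."""
    frame = aligned.frame
    cols = [f"{side}_{c}" for c in _CATS]
    table = frame.groupby("participant_id")[cols].mean() * 100.0
    out = {}
    for c, col in zip(_CATS, cols):
        vals = table[col]
        out[c] = {
            "mean": round(float(vals.mean()), 6),
            "sd": round(float(vals.std(ddof=1)) if len(vals) > 1 else 0.0, 6),
        }
    return out


def _participant_table(aligned: AlignedCorpus, side: str) -> pd.DataFrame:
    frame = aligned.frame
    cols = [f"{side}_{c}" for c in _CATS]
    table = frame.groupby("participant_id")[cols].mean() * 100.0
    table.columns = list(_CATS)
    return table


def _safe_correlation(a: pd.DataFrame, b: pd.DataFrame) -> dict:
    """Correlation matrix as nested dicts, dropping constant columns."""
    keep_a = [c for c in a.columns if a[c].std() > 0]
    keep_b = [c for c in b.columns if b[c].std() > 0]
    if not keep_a or not keep_b or len(a) < 3:
        return {}
    r = pearson_correlation(a[keep_a], b[keep_b])
    return {
        ra: {rb: round(float(r.loc[ra, rb]), 6) for rb in keep_b}
        for ra in keep_a
    }


def _comparison_cell(res: ComparisonResult) -> dict:
    return {
        "p1": round(res.p1, 6), "p2": round(res.p2, 6),
        "n1": res.n1, "n2": res.n2,
        "z": round(res.z, 6), "p_value": float(f"{res.p_value:.6g}"),
        "alpha_corrected": round(res.alpha_corrected, 8),
        "significant": bool(res.significant),
        "approximate": bool(res.approximate),
    }


def _metric_n(conf_cell: dict, metric: str) -> int:
    tp, fp, fn, tn = (conf_cell[k] for k in ("tp", "fp", "fn", "tn"))
    if metric in ("sensitivity", "f_score"):
        return tp + fn
    if metric == "specificity":
        return tn + fp
    if metric == "ppv":
        return tp + fp
    return tn + fn  # npv


def run_validation(config: RunConfig) -> RunReport:
    """Execute a full validation run and return its report."""
    with _stage("config"):
        config.validate()

    lexicons: dict[str, Lexicon] = {}
    with _stage("read-lexicons"):
        for tag, path in sorted(config.lexicons.items()):
            lexicons[tag] = read_lexicon(path)
    emoticons = sorted({
        e.pattern
        for lex in lexicons.values()
        for e in lex.entries
        if e.is_emoticon
    })

    with _stage("read-corpus"):
        docs = lio.read_corpus(config.corpus, emoticons=emoticons)
    with _stage("read-reference"):
        labels = lio.read_reference(config.reference)

    tagged: dict[str, TaggedCorpus] = {}
    with _stage("tag"):
        for tag, lex in lexicons.items():
            tagged[tag] = tag_corpus(lex, docs)
        for tag, path in sorted(config.predictions.items()):
            tagged[tag] = _tagged_from_tsv(tag, path)

    aligned: dict[str, AlignedCorpus] = {}
    with _stage("align"):
        for tag, tc in tagged.items():
            aligned[tag] = align(labels, tc, categories=_CATS)

    versions = sorted(tagged)
    report = _assemble_report(config, versions, aligned)

    if config.out_dir is not None:
        with _stage("write-report"):
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            (out / "report.json").write_text(
                report.to_json(), encoding="utf-8"
            )
            for name, table in report.render_tables().items():
                table.to_csv(out / f"{name}.csv", index=False)
    return report


def _assemble_report(
    config: RunConfig,
    versions: Sequence[str],
    aligned: Mapping[str, AlignedCorpus],
) -> RunReport:
    alpha_diag = bonferroni(config.alpha, config.family_diagnostic)
    alpha_f = bonferroni(config.alpha, config.family_f)

    metrics: dict[str, dict] = {}
    with _stage("metrics"):
        for v in versions:
            metrics[v] = {}
            for cat in _CATS:
                counts = confusion(aligned[v], cat)
                cell: dict[str, object] = {
                    "confusion": {
                        "tp": counts.tp, "fp": counts.fp,
                        "fn": counts.fn, "tn": counts.tn,
                    },
                    "prevalence": round(counts.prevalence, 8),
                }
                estimates = {}
                for name, fn in (
                    ("sensitivity", sensitivity), ("specificity", specificity),
                    ("ppv", ppv), ("npv", npv),
                ):
                    est = fn(counts, method=config.ci_method)
                    estimates[name] = est
                    cell[name] = {
                        "value": round(est.value, 6),
                        "ci_low": round(est.ci_low, 6),
                        "ci_high": round(est.ci_high, 6),
                        "n": est.n,
                    }
                f = f_score(estimates["ppv"].value,
                            estimates["sensitivity"].value)
                cell["f_score"] = {
                    "value": round(f.value, 6),
                    "ppv": round(f.ppv, 6),
                    "sensitivity": round(f.sensitivity, 6),
                    "n": counts.reference_positives,
                }
                metrics[v][cat] = cell

    comparisons: dict[str, dict] = {}
    with _stage("compare"):
        for metric in _DIAG_METRICS + ("f_score",):
            alpha_c = alpha_f if metric == "f_score" else alpha_diag
            comparisons[metric] = {}
            for cat in _CATS:
                comparisons[metric][cat] = {}
                for v1, v2 in itertools.combinations(versions, 2):
                    m1 = metrics[v1][cat][metric]
                    m2 = metrics[v2][cat][metric]
                    n1 = _metric_n(metrics[v1][cat]["confusion"], metric)
                    n2 = _metric_n(metrics[v2][cat]["confusion"], metric)
                    if n1 == 0 or n2 == 0:
                        continue
                    try:
                        res = two_proportion_test(
                            m1["value"], n1, m2["value"], n2,
                            alpha_corrected=alpha_c,
                            approximate=(metric == "f_score"),
                        )
                    except LexemoError:
                        continue
                    comparisons[metric][cat][f"{v1}_vs_{v2}"] = (
                        _comparison_cell(res)
                    )

    with _stage("percentages"):
        first = aligned[versions[0]]
        percentages = {"human": _percentage_summary(first, "ref")}
        for v in versions:
            percentages[v] = _percentage_summary(aligned[v], "pred")

    with _stage("correlations"):
        human_table = _participant_table(first, "ref")
        tables = {v: _participant_table(aligned[v], "pred")
                  for v in versions}
        correlations = {}
        for v in versions:
            correlations[f"{v}_vs_human"] = _safe_correlation(
                tables[v], human_table
            )
        for v1, v2 in itertools.combinations(versions, 2):
            correlations[f"{v1}_vs_{v2}"] = _safe_correlation(
                tables[v1], tables[v2]
            )

    data = {
        "provenance": {
            "tool": "lexemo",
            "config_hash": config.hash(),
            "seed": config.seed,
            "versions": list(versions),
            "ci_method": config.ci_method,
            "alpha": config.alpha,
            "bonferroni": {
                "diagnostic": {
                    "family_size": config.family_diagnostic,
                    "threshold": round(alpha_diag, 8),
                },
                "f_score": {
                    "family_size": config.family_f,
                    "threshold": round(alpha_f, 8),
                },
            },
        },
        "counts": {
            "participants": len(first.participants),
            "total_tokens": {
                v: aligned[v].total_tokens for v in versions
            },
        },
        "percentages": percentages,
        "metrics": metrics,
        "comparisons": comparisons,
        "correlations": correlations,
    }
    return RunReport(data)


def compare_versions(
    report: RunReport,
    pair: tuple[str, str],
    category: str,
    metric: str,
) -> ComparisonResult:
    """Recompute one pairwise two-proportion comparison from a report."""
    v1, v2 = pair
    for v in pair:
        if v not in report.versions:
            raise KeyError(f"version {v!r} not in report")
    if metric not in _DIAG_METRICS + ("f_score",):
        raise KeyError(f"unknown metric {metric!r}")
    if category not in _CATS:
        raise KeyError(f"unknown category {category!r}")
    m1 = report.metric(v1, category, metric)
    m2 = report.metric(v2, category, metric)
    c1 = report.metric(v1, category, "confusion")
    c2 = report.metric(v2, category, "confusion")
    prov = report.data["provenance"]["bonferroni"]
    alpha_c = (
        prov["f_score"]["threshold"] if metric == "f_score"
        else prov["diagnostic"]["threshold"]
    )
    return two_proportion_test(
        m1["value"], _metric_n(c1, metric),
        m2["value"], _metric_n(c2, metric),
        alpha_corrected=alpha_c,
        approximate=(metric == "f_score"),
    )
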