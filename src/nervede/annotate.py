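"""Gene-list annotation and report assembly.

DE results are intersected with user-supplied gene lists (e.g. pain-gene
databases, or a scored neural-proportion list where a score >= 0.5 flags
neurally enriched genes).  Matching is exact on uppercased symbols — alias
resolution is deliberately out of scope, mismatches are reported rather
than guessed.  Annotation never alters DE calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

log = logging.getLogger("nervede")

__all__ = ["GeneList", "read_gene_list", "intersect", "score_filter", "build_report"]


@dataclass
class GeneList:
    """A named symbol list, optionally scored (scores in [0, 1])."""

    name: str
    symbols: list[str]
    scores: dict[str, float] | None = None

    def __post_init__(self) -> None:
        norm = [s.strip().upper() for s in self.symbols]
        seen: set[str] = set()
        dedup: list[str] = []
        for s in norm:
            if s in seen:
                log.warning("gene list %r: duplicate symbol %s dropped", self.name, s)
                continue
            seen.add(s)
            dedup.append(s)
        self.symbols = dedup
        if self.scores is not None:
            self.scores = {k.strip().upper(): float(v) for k, v in self.scores.items()}

    def __contains__(self, symbol: str) -> bool:
        return symbol.strip().upper() in set(self.symbols)


def read_gene_list(path: str | Path, name: str | None = None) -> GeneList:
    """Read a one- or two-column TSV (symbol [, score])."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    symbols = df.iloc[:, 0].astype(str).tolist()
    scores = None
    if df.shape[1] >= 2:
        scores = {s: float(v) for s, v in zip(symbols, df.iloc[:, 1]) if pd.notna(v)}
    return GeneList(name=name or path.stem, symbols=symbols, scores=scores)


def intersect(de: pd.DataFrame, annotation: pd.DataFrame,
              lists: list[GeneList]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-DE-gene membership flags for each list, plus summary counts.

    ``de`` is a DE result table (indexed by gene_id with a ``call`` column);
    membership is evaluated on the called genes only.  Returns the annotated
    table and a summary with member counts and fractions per list and per
    call category.
    """
    called = de[de["call"] != "none"].copy()
    symbols = annotation.reindex(called.index)["symbol"].astype(str).str.upper()
    called["symbol"] = symbols
    summary_rows = []
    for gl in lists:
        members = set(gl.symbols)
        flags = symbols.isin(members)
        called[f"in_{gl.name}"] = flags.to_numpy()
        n_called = len(called)
        summary_rows.append({
            "list": gl.name, "category": "all",
            "members": int(flags.sum()),
            "de_genes": n_called,
            "fraction": float(flags.mean()) if n_called else 0.0,
        })
        for cat in ("male_50", "female_50", "male_75", "female_75"):
            sub = called["call"] == cat
            n = int(sub.sum())
            summary_rows.append({
                "list": gl.name, "category": cat,
                "members": int((flags & sub).sum()),
                "de_genes": n,
                "fraction": float(flags[sub].mean()) if n else 0.0,
            })
    return called, pd.DataFrame(summary_rows)


def score_filter(de: pd.DataFrame, annotation: pd.DataFrame, scored: GeneList,
                 threshold: float = 0.5) -> pd.DataFrame:
    """DE genes whose score in ``scored`` is >= ``threshold``.

    Listed genes without a score are excluded with a warning.
    """
    if scored.scores is None:
        raise ValueError(f"gene list {scored.name!r} carries no scores")
    called = de[de["call"] != "none"]
    symbols = annotation.reindex(called.index)["symbol"].astype(str).str.upper()
    listed = set(scored.symbols)
    keep = []
    for gid, sym in symbols.items():
        if sym not in listed:
            continue
        if sym not in scored.scores:
            log.warning("score_filter: %s listed in %r without a score, excluded",
                        sym, scored.name)
            continue
        if scored.scores[sym] >= threshold:
            keep.append(gid)
    out = called.loc[keep].copy()
    out["symbol"] = symbols.loc[keep]
    out[f"{scored.name}_score"] = [scored.scores[s] for s in out["symbol"]]
    return out


def build_report(de: pd.DataFrame, annotation: pd.DataFrame,
                 entropy: pd.Series | None = None,
                 truth: pd.DataFrame | None = None,
                 ) -> tuple[pd.DataFrame, dict]:
    """Assemble the master per-gene report and its category counts.

    Columns: symbol, chromosome, call, per-level p/q/fold/direction, SSMD,
    entropy when supplied; with a synthetic truth table the report gains the
    true class/direction and the counts gain a confusion summary (calls on
    genes of each truth class).  Report counts always equal the DE call
    partition — annotation adds columns, never rows or calls.
    """
    missing = [g for g in de.index if g not in annotation.index]
    if missing:
        raise KeyError(f"annotation missing for gene(s) {missing[:5]}")
    report = de.copy()
    report.insert(1, "symbol", annotation.reindex(de.index)["symbol"].to_numpy())
    report.insert(2, "chromosome",
                  annotation.reindex(de.index)["chromosome"].to_numpy())
    if entropy is not None:
        report["entropy"] = entropy.reindex(de.index).to_numpy()
    counts = {k: int((de["call"] == k).sum())
              for k in ("male_50", "female_50", "male_75", "female_75")}
    counts["total_called"] = sum(counts.values())
    if truth is not None:
        report["true_class"] = truth.reindex(de.index)["class"].to_numpy()
        report["true_direction"] = truth.reindex(de.index)["direction"].to_numpy()
        called = report["call"] != "none"
        confusion = (report[called].groupby("true_class")["call"]
                     .value_counts().to_dict())
        counts["confusion"] = {f"{tc}->{call}": n
                               for (tc, call), n in sorted(confusion.items())}
        counts["false_calls"] = int((report.loc[called, "true_class"] == "null").sum())
    log.info("build_report: %s", {k: v for k, v in counts.items()
                                  if k != "confusion"})
    return report, counts
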