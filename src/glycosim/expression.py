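"""Glycogene microarray ingestion and per-enzyme expression ratios.

Each model enzyme maps to one or more microarray probes (several genes can
encode one activity, and one gene may be covered by several probes).  The
enzyme-level expression for a condition is the plain mean over all mapped
probe signals; the between-condition ratio of those means feeds the
expression-constrained fit.  Present/Marginal/Absent calls are parsed as
metadata; by default all probes enter the mean regardless of call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = ["ProbeRecord", "EnzymeExpression", "ExpressionConstraint",
           "load_microarray", "load_enzyme_mapping", "enzyme_expression",
           "ratios_for_constraint", "DEFAULT_EXEMPT"]

#: enzymes never constrained by expression ratios: GnTV has a defective
#: probe set and ManI has no probe on the chip.
DEFAULT_EXEMPT = frozenset({"GnTV", "ManI"})


@dataclass
class ProbeRecord:
    probe_id: str
    gene: str
    signal: dict[str, float]            # condition -> replicate-mean signal
    call: dict[str, str] = field(default_factory=dict)  # P | M | A


@dataclass
class EnzymeExpression:
    enzyme: str
    probes: list[str]
    mean_signal: dict[str, float]
    ratio: float | None                 # condition B / condition A


@dataclass
class ExpressionConstraint:
    ratios: dict[str, float]            # enzyme -> B/A activity ratio
    exempt: frozenset[str] = DEFAULT_EXEMPT


def load_microarray(path_or_df, conditions: tuple[str, str] = ("low", "high"),
                    ) -> list[ProbeRecord]:
    """Load a probe signal table.

    Expects columns ``probe_id``, ``gene``, and per condition either one
    ``signal_<cond>`` column or replicate columns ``signal_<cond>_rep*``
    (averaged), plus optional ``call_<cond>`` columns.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df
    else:
        df = pd.read_csv(path_or_df, sep=None, engine="python")
    required = {"probe_id", "gene"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    records = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        signal, call = {}, {}
        for cond in conditions:
            reps = [c for c in df.columns
                    if c == f"signal_{cond}" or c.startswith(f"signal_{cond}_rep")]
            if not reps:
                raise ValueError(f"no signal column for condition {cond!r}")
            try:
                vals = [float(row[c]) for c in reps]
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"non-numeric signal on line {lineno}: {exc}") from exc
            if any(v < 0 for v in vals):
                raise ValueError(f"negative signal on line {lineno}")
            signal[cond] = sum(vals) / len(vals)
            if f"call_{cond}" in df.columns:
                c = str(row[f"call_{cond}"]).strip()
                if c not in {"P", "M", "A"}:
                    raise ValueError(
                        f"invalid call {c!r} on line {lineno}")
                call[cond] = c
        records.append(ProbeRecord(str(row["probe_id"]), str(row["gene"]),
                                   signal, call))
    return records


def load_enzyme_mapping(path=None) -> dict[str, list[str]]:
    """Enzyme -> probe-id list (the packaged mapping by default)."""
    if path is None:
        text = resources.files("glycosim.data").joinpath(
            "enzyme_genes.tsv").read_text()
        lines = [ln.split("\t") for ln in text.splitlines()[1:] if ln.strip()]
        mapping: dict[str, list[str]] = {}
        for f in lines:
            mapping.setdefault(f[0], []).append(f[1])
        return mapping
    df = pd.read_csv(path, sep="\t", dtype=str)
    mapping = {}
    for _, row in df.iterrows():
        mapping.setdefault(row["enzyme"], []).append(str(row["probe_id"]))
    return mapping


def load_packaged_microarray() -> list[ProbeRecord]:
    """The packaged LNCaP low/high-passage glycogene signal table."""
    with resources.files("glycosim.data").joinpath("enzyme_genes.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"probe_id": str})
    df = df.rename(columns={"signal_low": "signal_low",
                            "signal_high": "signal_high"})
    return load_microarray(df)


def enzyme_expression(records: list[ProbeRecord],
                      mapping: dict[str, list[str]],
                      conditions: tuple[str, str] = ("low", "high"),
                      exclude_absent: bool = False) -> list[EnzymeExpression]:
    """Per-enzyme mean signal across all mapped probes and its B/A ratio.

    Probes mapping to the same gene count as separate signals.  With
    ``exclude_absent`` probes called 'A' in a condition are dropped from
    that condition's mean.
    """
    by_probe: dict[str, list[ProbeRecord]] = {}
    for rec in records:
        by_probe.setdefault(rec.probe_id, []).append(rec)
    out = []
    for enzyme, probe_ids in mapping.items():
        recs = [r for pid in probe_ids for r in by_probe.get(pid, [])]
        means: dict[str, float] = {}
        for cond in conditions:
            vals = [r.signal[cond] for r in recs
                    if not (exclude_absent and r.call.get(cond) == "A")]
            means[cond] = sum(vals) / len(vals) if vals else float("nan")
        a, b = means[conditions[0]], means[conditions[1]]
        ratio = (b / a) if recs and a and a > 0 else None
        out.append(EnzymeExpression(enzyme, [r.probe_id for r in recs],
                                    means, ratio))
    return out


def ratios_for_constraint(expressions: list[EnzymeExpression],
                          exempt: frozenset[str] | set[str] = DEFAULT_EXEMPT,
                          ) -> ExpressionConstraint:
    """Build the fit constraint: B/A ratios for every non-exempt mapped
    enzyme; enzymes with a zero or undefined denominator are auto-exempted."""
    exempt = set(exempt)
    ratios = {}
    for e in expressions:
        if e.enzyme in exempt:
            continue
        if e.ratio is None or not (e.ratio > 0):
            import warnings
            warnings.warn(f"enzyme {e.enzyme} has no usable expression "
                          "ratio; exempting from the constraint")
            exempt.add(e.enzyme)
            continue
        ratios[e.enzyme] = e.ratio
    return ExpressionConstraint(ratios, frozenset(exempt))
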