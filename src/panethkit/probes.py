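"""Constrained probe-panel selection for multiplexed FISH.

Candidates are filtered on minimum transcript length (short transcripts,
e.g. the alpha-defensins, cannot carry enough unique probe sequence) and on
expected-signal bounds (extremely highly expressed genes such as Lyz1
saturate detection).  The panel is then assembled greedily under a probe
count limit and a total-expected-signal cap, prioritizing the most
important cell-type classes first.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import ValidationError

__all__ = ["ProbeCandidate", "filter_candidates", "select_panel"]


@dataclass(frozen=True)
class ProbeCandidate:
    gene: str
    transcript_length: float      # nt
    expected_signal: float        # abstract vendor signal units
    priority_class: int = 0       # lower = more important (PC markers first)
    cell_type: str = ""

    def __post_init__(self) -> None:
        if self.transcript_length < 0 or self.expected_signal < 0:
            raise ValidationError(
                f"{self.gene}: length and signal must be >= 0")


def filter_candidates(
    candidates,
    min_len: float,
    min_sig: float,
    max_sig: float,
) -> tuple[list[ProbeCandidate], pd.DataFrame]:
    """Keep candidates with length >= min_len and signal in [min_sig, max_sig].

    Returns the kept list (input order preserved) and a rejection log with
    the first violated rule per rejected candidate.
    """
    if min_sig > max_sig:
        raise ValidationError("min_sig must be <= max_sig")
    kept: list[ProbeCandidate] = []
    rejected = []
    for c in candidates:
        if c.transcript_length < min_len:
            rejected.append((c.gene, "min_length", c.transcript_length))
        elif c.expected_signal < min_sig:
            rejected.append((c.gene, "min_signal", c.expected_signal))
        elif c.expected_signal > max_sig:
            rejected.append((c.gene, "max_signal", c.expected_signal))
        else:
            kept.append(c)
    log = pd.DataFrame(rejected, columns=["gene", "rule", "value"])
    return kept, log


def select_panel(
    kept,
    max_probes: int = 100,
    total_signal_cap: float = float("inf"),
) -> list[ProbeCandidate]:
    """Greedy panel under count and total-signal constraints.

    Candidates are scanned in order (priority_class asc, expected_signal
    asc, gene name asc); a candidate is added while the panel is below
    ``max_probes`` and adding it keeps the running signal within the cap.
    Deterministic for identical inputs.
    """
    kept = list(kept)
    if not kept:
        raise ValidationError("no candidates to select from")
    order = sorted(kept, key=lambda c: (c.priority_class, c.expected_signal,
                                        c.gene))
    panel: list[ProbeCandidate] = []
    running = 0.0
    for c in order:
        if len(panel) >= max_probes:
            break
        if running + c.expected_signal <= total_signal_cap:
            panel.append(c)
            running += c.expected_signal
    if not panel:
        raise ValidationError(
            "no feasible panel: every candidate exceeds the signal cap")
    return panel


def coverage_counts(panel) -> pd.Series:
    """Probes per cell-type tag in a panel."""
    return pd.Series([c.cell_type for c in panel]).value_counts()


def read_candidates(path) -> list[ProbeCandidate]:
    """Read a candidate TSV (gene, transcript_length, expected_signal,
    optional priority_class, cell_type)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "transcript_length", "expected_signal"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"candidate table missing columns {sorted(missing)}")
    out = []
    for _, r in df.iterrows():
        out.append(ProbeCandidate(
            gene=str(r["gene"]),
            transcript_length=float(r["transcript_length"]),
            expected_signal=float(r["expected_signal"]),
            priority_class=int(r.get("priority_class", 0)),
            cell_type=str(r.get("cell_type", "")),
        ))
    return out


def panel_frame(panel) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene": c.gene,
        "transcript_length": c.transcript_length,
        "expected_signal": c.expected_signal,
        "priority_class": c.priority_class,
        "cell_type": c.cell_type,
    } for c in panel])
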