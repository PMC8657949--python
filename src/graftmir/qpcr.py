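"""Stem-loop RT-qPCR relative quantification and expression binning.

Ct tables follow the schema ``sample_id, assay, bio_rep, tech_rep, ct``.
Technical replicates are averaged first; then per biological replicate
dCt = mean Ct(assay) - mean Ct(reference), summarized as mean +/- sd
over biological replicates.  The nuclear small RNA U6 is the default
internal reference; larger dCt means lower abundance, and the relative
quantity 2**(-dCt) restores a monotone abundance scale.

Expression binning converts read counts in a reference library to
reads-per-million and labels each miRNA by log10(RPM) against ordered
bin edges (five classes from extremely_low to ultra_high).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("graftmir")

CT_COLUMNS = ("sample_id", "assay", "bio_rep", "tech_rep", "ct")

EXPRESSION_LABELS = ("extremely_low", "low", "medium", "high", "ultra_high")
DEFAULT_BIN_EDGES = (-1.0, 0.5, 1.5, 2.5)


@dataclass
class DeltaCtResult:
    """Per-biological-replicate dCt values and their summary."""

    assay: str
    reference: str
    per_replicate: pd.DataFrame  # sample_id, bio_rep, ct_assay, ct_reference, delta_ct
    mean: float
    sd: float

    def relative_quantity(self) -> float:
        return relative_quantity(self.mean)


def load_ct_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table lacks column(s) {missing}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be > 0")
    return table


def delta_ct(
    records: pd.DataFrame, assay: str, reference: str = "U6"
) -> DeltaCtResult:
    """dCt = Ct(assay) - Ct(reference) per biological replicate.

    Technical replicates are averaged before differencing.  Biological
    replicates missing the reference assay are skipped with a warning;
    if none remain an error is raised.
    """
    tech_mean = (
        records.groupby(["sample_id", "bio_rep", "assay"])["ct"]
        .mean()
        .unstack("assay")
    )
    if assay not in tech_mean.columns:
        raise ValueError(f"assay {assay!r} absent from Ct table")
    if reference not in tech_mean.columns:
        raise ValueError(f"reference assay {reference!r} absent from Ct table")
    sub = tech_mean[[assay, reference]].dropna(subset=[assay])
    missing_ref = sub[sub[reference].isna()]
    for sample_id, bio_rep in missing_ref.index:
        log.warning(
            "delta_ct: %s bio_rep %s lacks reference %s; skipped",
            sample_id, bio_rep, reference,
        )
    sub = sub.dropna(subset=[reference])
    if sub.empty:
        raise ValueError(
            f"no biological replicate carries both {assay!r} and {reference!r}"
        )
    per_rep = sub.reset_index().rename(
        columns={assay: "ct_assay", reference: "ct_reference"}
    )
    per_rep["delta_ct"] = per_rep["ct_assay"] - per_rep["ct_reference"]
    values = per_rep["delta_ct"].to_numpy()
    return DeltaCtResult(
        assay=assay,
        reference=reference,
        per_replicate=per_rep,
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
    )


def relative_quantity(dct: float) -> float:
    """2**(-dCt): positive, monotone decreasing in dCt."""
    return float(2.0 ** (-dct))


def bin_expression(
    counts: Mapping[str, int],
    library_size: int,
    edges: Sequence[float] = DEFAULT_BIN_EDGES,
    labels: Sequence[str] = EXPRESSION_LABELS,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Label each miRNA's abundance class and the class fractions.

    RPM = 1e6 * count / library_size; the label is chosen by comparing
    log10(RPM + eps) with the ordered edges, where eps is the RPM of
    half a read (a deterministic floor).  A count of zero is always
    extremely_low.  Fractions over all miRNAs sum to 1.
    """
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    edges = [float(e) for e in edges]
    if len(labels) != len(edges) + 1:
        raise ValueError("need exactly one more label than bin edges")
    eps = 1e6 * 0.5 / library_size
    rows = []
    for name in sorted(counts):
        count = int(counts[name])
        rpm = 1e6 * count / library_size
        if count == 0:
            label = labels[0]
        else:
            label = labels[int(np.searchsorted(edges, math.log10(rpm + eps), side="right"))]
        rows.append(
            {"mirna": name, "count": count, "rpm": rpm, "class": label}
        )
    table = pd.DataFrame(rows, columns=["mirna", "count", "rpm", "class"])
    n = len(table)
    fractions = {
        label: (float((table["class"] == label).sum()) / n if n else 0.0)
        for label in labels
    }
    return table, fractions
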