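"""Target-set construction from differential-expression tables and
behavioral classification of animals.

The target gene set for the network analysis is built from two contrasts:
genes significantly altered by chronic social isolation (single-housed Sh
versus group-housed Gh) intersected with genes significantly different
between isolated and fluoxetine-treated isolated animals (Sh versus
Sh+Flx) — the "stress-affected, Flx-normalized" genes.  Sign convention
throughout: log2 fold change is positive when expression is higher in the
first-named condition of the contrast.

Behavioral rules: an animal is anxious in the homecage assay when its
shelter time exceeds the control-group mean by more than twice the
control SEM, and anxious in the open field when its center-to-periphery
time ratio falls below 0.25.  Both comparisons are strict.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, ValidationError

log = logging.getLogger(__name__)

DE_COLUMNS = ["gene", "log2fc", "p", "adj_p"]

#: open-field anxiety cutoff on the center/periphery time ratio
OPENFIELD_RATIO_CUTOFF = 0.25


def read_de_table(source: Union[str, Path], contrast: Optional[str] = None) -> pd.DataFrame:
    """Read a differential-expression TSV with columns gene, log2fc, p, adj_p.

    Gene symbols are uppercased; duplicate genes raise; p/adj_p outside
    [0, 1] raise; rows where adj_p < p are logged (external tables are not
    assumed internally consistent) but kept.
    """
    table = pd.read_csv(source, sep="\t")
    missing = [c for c in DE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{source}: missing column(s) {missing}; need {DE_COLUMNS}")
    table = table[DE_COLUMNS].copy()
    table["gene"] = table["gene"].astype(str).str.strip().str.upper()
    if table["gene"].duplicated().any():
        dupes = table.loc[table["gene"].duplicated(), "gene"].head(5).tolist()
        raise ValidationError(f"{source}: duplicate gene symbol(s), e.g. {dupes}")
    for col in ("p", "adj_p"):
        vals = table[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)) or np.any(vals < 0) or np.any(vals > 1):
            raise ValidationError(f"{source}: column {col!r} must lie in [0, 1]")
    n_inverted = int((table["adj_p"] < table["p"]).sum())
    if n_inverted:
        log.warning("%s: %d row(s) with adj_p < p (kept as-is)", source, n_inverted)
    table.attrs["contrast"] = contrast
    return table


def significant_genes(table: pd.DataFrame, alpha: float = 0.05) -> set[str]:
    """Genes whose BH-adjusted p is at or below ``alpha`` (default 0.05)."""
    if not 0 < alpha <= 1:
        raise ParameterError(f"alpha must be in (0, 1], got {alpha}")
    if "adj_p" not in table.columns:
        raise FormatError("table lacks an 'adj_p' column")
    return set(table.loc[table["adj_p"] <= alpha, "gene"])


def flx_normalized_set(
    sig_stress: set[str],
    sig_treatment: set[str],
    direction_tables: Optional[tuple[pd.DataFrame, pd.DataFrame]] = None,
    require_consistent_direction: bool = False,
) -> set[str]:
    """Stress-affected, treatment-normalized genes: the two-set intersection.

    By default this is the plain intersection of the significant genes from
    the stress contrast (Sh vs Gh) and the treatment contrast (Sh vs
    Sh+Flx).  With ``require_consistent_direction``, a gene is additionally
    required to move the same way in both contrasts (both positive = raised
    by isolation and brought back down by fluoxetine, or both negative),
    using the first-named-condition-positive sign convention.
    """
    intersection = sig_stress & sig_treatment
    if not require_consistent_direction:
        return intersection
    if direction_tables is None:
        raise ParameterError("direction check requested but no fold-change tables supplied")
    stress_fc = dict(zip(direction_tables[0]["gene"], direction_tables[0]["log2fc"]))
    treat_fc = dict(zip(direction_tables[1]["gene"], direction_tables[1]["log2fc"]))
    kept = set()
    for g in intersection:
        if g not in stress_fc or g not in treat_fc:
            continue
        if math.copysign(1.0, stress_fc[g]) == math.copysign(1.0, treat_fc[g]):
            kept.add(g)
    return kept


def three_way_overlap(
    set_a: set[str], set_b: set[str], set_c: set[str]
) -> dict[str, int]:
    """Cardinalities of the 7 Venn regions of three gene sets, plus totals.

    Region keys name membership: ``a_only``, ``ab``, ``abc``, ... ; the
    regions partition the union, so their counts always sum to ``union``.
    """
    regions = {
        "a_only": len(set_a - set_b - set_c),
        "b_only": len(set_b - set_a - set_c),
        "c_only": len(set_c - set_a - set_b),
        "ab": len((set_a & set_b) - set_c),
        "ac": len((set_a & set_c) - set_b),
        "bc": len((set_b & set_c) - set_a),
        "abc": len(set_a & set_b & set_c),
    }
    regions["total_a"] = len(set_a)
    regions["total_b"] = len(set_b)
    regions["total_c"] = len(set_c)
    regions["union"] = len(set_a | set_b | set_c)
    return regions


def classify_anxious_shelter(
    values: Mapping[str, float], control_values: Sequence[float]
) -> dict[str, bool]:
    """Homecage shelter-time anxiety calls against the control group.

    An animal is anxious iff its shelter time strictly exceeds
    mean(control) + 2 * SEM(control), with SEM = sd / sqrt(n) using the
    n-1 sample standard deviation.  More shelter time means less
    exploration, so the rule is upper-tailed.
    """
    controls = np.asarray(list(control_values), dtype=float)
    if controls.size < 2:
        raise ParameterError("need >= 2 control animals to define the SEM")
    sem = controls.std(ddof=1) / math.sqrt(controls.size)
    cutoff = controls.mean() + 2.0 * sem
    return {animal: bool(v > cutoff) for animal, v in values.items()}


def classify_anxious_openfield(ratio: float) -> bool:
    """Open-field anxiety call: center/periphery time ratio strictly below 0.25."""
    if not math.isfinite(ratio) or ratio < 0:
        raise ValidationError(f"center/periphery ratio must be finite and >= 0, got {ratio}")
    return ratio < OPENFIELD_RATIO_CUTOFF


def read_behavior_table(source: Union[str, Path]) -> pd.DataFrame:
    """Read the behavioral CSV: animal, group, shelter_time_s, center_periphery_ratio."""
    table = pd.read_csv(source)
    required = ["animal", "group", "shelter_time_s", "center_periphery_ratio"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"{source}: missing column(s) {missing}")
    shelter = table["shelter_time_s"].to_numpy(dtype=float)
    if np.any(shelter < 0) or np.any(shelter > 900):
        raise ValidationError(f"{source}: shelter_time_s must lie in [0, 900] seconds")
    return table


def classify_cohort(
    behavior: pd.DataFrame, control_group: str = "Gh"
) -> pd.DataFrame:
    """Apply both anxiety classifiers to a behavioral table.

    Shelter calls use the named control group as the reference; open-field
    calls are per-animal thresholding.  Returns the table with added
    boolean columns ``anxious_shelter`` and ``anxious_openfield``.
    """
    controls = behavior.loc[behavior["group"] == control_group, "shelter_time_s"]
    if len(controls) < 2:
        raise ParameterError(f"control group {control_group!r} has fewer than 2 animals")
    values = dict(zip(behavior["animal"], behavior["shelter_time_s"]))
    shelter_calls = classify_anxious_shelter(values, controls.tolist())
    out = behavior.copy()
    out["anxious_shelter"] = out["animal"].map(shelter_calls)
    out["anxious_openfield"] = [
        classify_anxious_openfield(r) for r in out["center_periphery_ratio"]
    ]
    return out


def write_gene_set(genes: Iterable[str], destination: Union[str, Path]) -> None:
    """One gene symbol per line, sorted."""
    Path(destination).write_text("\n".join(sorted(set(genes))) + "\n", encoding="utf-8")


def read_gene_set(source: Union[str, Path]) -> set[str]:
    """Read a one-symbol-per-line gene list, normalizing case."""
    lines = Path(source).read_text(encoding="utf-8").splitlines()
    return {ln.strip().upper() for ln in lines if ln.strip()}
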