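"""Droplet digital PCR (ddPCR) import, Poisson quantification and housekeeper normalization.

ddPCR partitions a reaction into ~20,000 nanolitre-scale droplets and reads
each droplet as positive or negative for the target amplicon.  Because template
molecules distribute over droplets approximately Poisson, the concentration in
copies/µL is recovered from the positive fraction as

    c = -ln(1 - k/n) / v

with k positive droplets out of n and v the droplet volume in µL.  Exported
wells may carry either raw droplet counts or an already-computed concentration;
both are accepted.  Technical replicate wells are averaged per (sample, target)
and every target is expressed relative to the EEF2 housekeeping gene, yielding
the dimensionless normalized levels that all downstream marker and survival
analyses consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "DropletWell",
    "NormalizedLevel",
    "DEFAULT_DIALECT",
    "DEFAULT_DROPLET_VOLUME_NL",
    "DdpcrError",
    "SaturationError",
    "read_ddpcr_csv",
    "droplet_to_concentration",
    "merge_replicates",
    "normalize_to_housekeeper",
    "write_levels_csv",
]

#: QX200 EvaGreen droplet volume convention, nanolitres.
DEFAULT_DROPLET_VOLUME_NL = 0.85

#: Default column-name mapping for well exports (QuantaSoft header names vary
#: by version, so the mapping is configurable).
DEFAULT_DIALECT: Mapping[str, str] = {
    "sample_id": "sample",
    "target": "target",
    "replicate": "replicate",
    "positive_droplets": "positives",
    "total_droplets": "total",
    "copies_per_ul": "concentration",
}


class DdpcrError(ValueError):
    """Validation or computation error in the ddPCR stage."""


class SaturationError(DdpcrError):
    """All droplets positive: the Poisson estimate is undefined."""


@dataclass(frozen=True)
class DropletWell:
    """One ddPCR well: one sample x target x technical replicate.

    Either raw droplet counts (``positive_droplets``/``total_droplets``) or a
    precomputed ``copies_per_ul`` must be present.
    """

    sample_id: str
    target: str
    replicate: int = 1
    positive_droplets: int | None = None
    total_droplets: int | None = None
    copies_per_ul: float | None = None

    def __post_init__(self) -> None:
        has_counts = self.positive_droplets is not None and self.total_droplets is not None
        if not has_counts and self.copies_per_ul is None:
            raise DdpcrError(
                f"well {self.sample_id}/{self.target}: needs droplet counts or copies_per_ul"
            )
        if has_counts:
            if self.positive_droplets < 0 or self.total_droplets < 0:
                raise DdpcrError(
                    f"well {self.sample_id}/{self.target}: negative droplet count"
                )
            if self.positive_droplets > self.total_droplets:
                raise DdpcrError(
                    f"well {self.sample_id}/{self.target}: positive droplets exceed total"
                )
        if self.copies_per_ul is not None:
            if not math.isfinite(self.copies_per_ul) or self.copies_per_ul < 0:
                raise DdpcrError(
                    f"well {self.sample_id}/{self.target}: copies_per_ul must be finite and >= 0"
                )
        if self.replicate < 1:
            raise DdpcrError(f"well {self.sample_id}/{self.target}: replicate must be >= 1")

    def concentration(self, droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL) -> float:
        """Concentration in copies/µL, from counts if present else as exported."""
        if self.positive_droplets is not None and self.total_droplets is not None:
            return droplet_to_concentration(
                self.positive_droplets, self.total_droplets, droplet_volume_nl
            )
        return float(self.copies_per_ul)


@dataclass(frozen=True)
class NormalizedLevel:
    """Dimensionless target level: target copies/µL divided by housekeeper copies/µL."""

    sample_id: str
    target: str
    level: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.level) or self.level < 0:
            raise DdpcrError(f"{self.sample_id}/{self.target}: level must be finite and >= 0")


def droplet_to_concentration(
    positive: int, total: int, droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
) -> float:
    """Poisson-correct a positive-droplet count into copies/µL.

    Parameters
    ----------
    positive, total
        Positive and total accepted droplet counts for the well.
    droplet_volume_nl
        Single-droplet volume in nanolitres (default 0.85, the QX200 EvaGreen
        convention).

    Returns
    -------
    float
        Estimated concentration ``-ln(1 - positive/total) / (v_nl * 1e-3)``
        in copies per microlitre.

    Raises
    ------
    SaturationError
        If every droplet is positive (the log diverges); saturated wells are
        rejected rather than clipped because clipping would bias downstream
        ratios.
    DdpcrError
        If ``total`` is zero, counts are negative or inconsistent, or the
        droplet volume is not positive.
    """
    if droplet_volume_nl <= 0:
        raise DdpcrError("droplet volume must be positive")
    if total <= 0:
        raise DdpcrError("total droplet count must be positive")
    if positive < 0 or positive > total:
        raise DdpcrError("need 0 <= positive <= total")
    if positive == total:
        raise SaturationError(
            f"all {total} droplets positive: concentration undefined (saturated well)"
        )
    volume_ul = droplet_volume_nl * 1e-3
    return -math.log1p(-positive / total) / volume_ul


def read_ddpcr_csv(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> list[DropletWell]:
    """Read a ddPCR well export (RFC-4180 CSV with header) into wells.

    ``dialect`` maps the canonical field names (keys of ``DEFAULT_DIALECT``)
    to the column names actually present in the file; count and concentration
    columns are each optional as long as one of the two forms is present.
    Rows with unparseable numerics are rejected with their row index named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ddPCR export not found: {path}")
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)

    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]

    required = ("sample_id", "target")
    for key in required:
        if mapping[key] not in df.columns:
            raise DdpcrError(f"missing mapped column '{mapping[key]}' for field '{key}'")
    optional = ("replicate", "positive_droplets", "total_droplets", "copies_per_ul")
    present = {k: mapping[k] for k in optional if mapping[k] in df.columns}
    if not (
        {"positive_droplets", "total_droplets"} <= present.keys()
        or "copies_per_ul" in present
    ):
        raise DdpcrError(
            "export must provide droplet count columns or a concentration column"
        )

    wells: list[DropletWell] = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 1  # 1-based data-row index for error messages

        def _num(key: str, cast):
            col = present.get(key)
            if col is None:
                return None
            raw = row[col]
            if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
                return None
            try:
                return cast(float(raw)) if cast is int else cast(raw)
            except (TypeError, ValueError) as exc:
                raise DdpcrError(f"row {rownum}: unparseable value {raw!r} in column '{col}'") from exc

        try:
            wells.append(
                DropletWell(
                    sample_id=str(row[mapping["sample_id"]]).strip(),
                    target=str(row[mapping["target"]]).strip(),
                    replicate=_num("replicate", int) or 1,
                    positive_droplets=_num("positive_droplets", int),
                    total_droplets=_num("total_droplets", int),
                    copies_per_ul=_num("copies_per_ul", float),
                )
            )
        except DdpcrError as exc:
            raise DdpcrError(f"row {rownum}: {exc}") from exc
    return wells


def merge_replicates(
    wells: Iterable[DropletWell],
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
) -> pd.DataFrame:
    """Average technical replicate concentrations per (sample, target).

    Returns a tidy frame with columns ``sample_id, target, copies_per_ul,
    n_replicates, replicate_cv`` where ``replicate_cv`` is the coefficient of
    variation across replicates (0 for singletons) — logged rather than used
    to exclude discordant duplicates.
    """
    rows = [
        (w.sample_id, w.target, w.concentration(droplet_volume_nl)) for w in wells
    ]
    if not rows:
        return pd.DataFrame(
            columns=["sample_id", "target", "copies_per_ul", "n_replicates", "replicate_cv"]
        )
    df = pd.DataFrame(rows, columns=["sample_id", "target", "copies_per_ul"])
    g = df.groupby(["sample_id", "target"], sort=True)["copies_per_ul"]
    out = g.agg(copies_per_ul="mean", n_replicates="size", _sd=lambda s: s.std(ddof=1)).reset_index()
    mean = out["copies_per_ul"]
    out["replicate_cv"] = (out.pop("_sd") / mean.where(mean > 0)).fillna(0.0)
    return out


def normalize_to_housekeeper(
    concentrations: pd.DataFrame, housekeeper: str = "EEF2"
) -> list[NormalizedLevel]:
    """Express every target as a ratio to the housekeeper, per sample.

    ``concentrations`` is the output of :func:`merge_replicates` (or any frame
    with ``sample_id, target, copies_per_ul``).  Housekeeper rows are consumed
    as denominators and excluded from the output.

    Raises
    ------
    DdpcrError
        If a sample lacks a housekeeper measurement or its housekeeper
        concentration is zero (the ratio is undefined); both errors name the
        offending sample.
    """
    hk = concentrations[concentrations["target"] == housekeeper]
    hk_by_sample = dict(zip(hk["sample_id"], hk["copies_per_ul"]))
    levels: list[NormalizedLevel] = []
    targets = concentrations[concentrations["target"] != housekeeper]
    for _, row in targets.iterrows():
        sample = row["sample_id"]
        if sample not in hk_by_sample:
            raise DdpcrError(f"sample '{sample}' has no {housekeeper} measurement")
        denom = hk_by_sample[sample]
        if denom == 0:
            raise DdpcrError(
                f"sample '{sample}': {housekeeper} concentration is zero, ratio undefined"
            )
        levels.append(
            NormalizedLevel(sample_id=sample, target=row["target"], level=row["copies_per_ul"] / denom)
        )
    return levels


def write_levels_csv(levels: Sequence[NormalizedLevel], path: str | Path) -> None:
    """Write normalized levels as tidy CSV (sample_id, target, level)."""
    pd.DataFrame(
        [(lv.sample_id, lv.target, lv.level) for lv in levels],
        columns=["sample_id", "target", "level"],
    ).to_csv(path, index=False)
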