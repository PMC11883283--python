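"""Poisson quantification of droplet-digital PCR with QC gates.

In ddPCR a reaction is partitioned into ~20,000 nanoliter droplets; the
fraction of droplets with no amplification estimates the Poisson mean of
template copies per droplet, lambda = -ln(negatives/accepted), from which
the input concentration in copies/ul follows. Wells must clear the
study's acceptance gates: more than 10,000 accepted droplets, more than
1,000 negative droplets, and more positives than the matched no-reverse-
transcriptase control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "DropletWell",
    "Quantification",
    "QCResult",
    "qc_gate",
    "poisson_concentration",
    "normalized_ratio",
    "pool_wells",
    "read_well_table",
]

MIN_ACCEPTED = 10_000
MIN_NEGATIVES = 1_000
DEFAULT_DROPLET_VOLUME_NL = 0.85  # QX200 droplet volume convention


@dataclass(frozen=True)
class DropletWell:
    """One droplet well after thresholding: totals, positives, metadata."""

    well_id: str
    target: str
    accepted_droplets: int
    positive_droplets: int
    dilution_factor: float = 1.0
    sample: str = ""
    is_no_rt_control: bool = False

    def __post_init__(self) -> None:
        if self.accepted_droplets <= 0:
            raise ValueError(f"well {self.well_id}: accepted_droplets must be > 0")
        if not (0 <= self.positive_droplets <= self.accepted_droplets):
            raise ValueError(
                f"well {self.well_id}: positives must lie in [0, accepted]"
            )
        if self.dilution_factor < 1:
            raise ValueError(f"well {self.well_id}: dilution_factor must be >= 1")

    @property
    def negative_droplets(self) -> int:
        return self.accepted_droplets - self.positive_droplets


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reasons: tuple[str, ...] = ()


@dataclass(frozen=True)
class Quantification:
    """Estimated copies per droplet and per ul of input material."""

    lam: float  # mean copies per droplet
    concentration: float  # copies/ul, dilution-corrected
    qc: QCResult
    target: str = ""
    sample: str = ""


def qc_gate(well: DropletWell, no_rt: DropletWell | None = None) -> QCResult:
    """Apply the well-acceptance gates; reports reasons, never raises.

    Gates (all strict, as printed on the instrument workflow): accepted
    droplets > 10,000; negative droplets > 1,000; positives strictly
    greater than the matched no-RT control's positives (when provided).
    """
    reasons = []
    if well.accepted_droplets <= MIN_ACCEPTED:
        reasons.append("low_droplets")
    if well.negative_droplets <= MIN_NEGATIVES:
        reasons.append("low_negatives")
    if no_rt is not None and well.positive_droplets <= no_rt.positive_droplets:
        reasons.append("not_above_no_rt")
    return QCResult(passed=not reasons, reasons=tuple(reasons))


def poisson_concentration(
    well: DropletWell,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
    no_rt: DropletWell | None = None,
) -> Quantification:
    """Poisson estimate of template concentration from droplet counts.

    lambda = -ln(negatives / accepted); concentration in copies/ul of the
    reaction is lambda / (droplet volume in ul), multiplied by the
    dilution factor to report the input-material concentration. A fully
    positive well is saturated and cannot be quantified.
    """
    if droplet_volume_nl <= 0:
        raise ValueError("droplet volume must be positive")
    if well.positive_droplets == well.accepted_droplets:
        raise ValueError(
            f"well {well.well_id}: saturated_assay (no negative droplets)"
        )
    lam = -math.log(well.negative_droplets / well.accepted_droplets)
    conc = lam / (droplet_volume_nl * 1e-3) * well.dilution_factor
    return Quantification(
        lam=lam,
        concentration=conc,
        qc=qc_gate(well, no_rt),
        target=well.target,
        sample=well.sample,
    )


def pool_wells(wells: list[DropletWell]) -> DropletWell:
    """Merge replicate wells of one sample/target by summing droplet counts.

    Pooling happens before the Poisson estimate (counts are added, lambdas
    are never averaged), so the estimate from a split well equals the
    estimate from the unsplit one.
    """
    if not wells:
        raise ValueError("no wells to pool")
    first = wells[0]
    for w in wells[1:]:
        if w.target != first.target or w.sample != first.sample:
            raise ValueError("can only pool wells of one sample/target")
        if w.dilution_factor != first.dilution_factor:
            raise ValueError("can only pool wells at the same dilution")
    return DropletWell(
        well_id="+".join(w.well_id for w in wells),
        target=first.target,
        accepted_droplets=sum(w.accepted_droplets for w in wells),
        positive_droplets=sum(w.positive_droplets for w in wells),
        dilution_factor=first.dilution_factor,
        sample=first.sample,
        is_no_rt_control=first.is_no_rt_control,
    )


def normalized_ratio(target: Quantification, reference: Quantification) -> float:
    """Target concentration over reference-gene concentration.

    Both quantifications must pass QC; concentrations are already
    dilution-corrected, so a reference assayed at 1:10 dilution is
    compared on the input-material scale.
    """
    if not target.qc.passed:
        raise ValueError(f"target failed QC: {target.qc.reasons}")
    if not reference.qc.passed:
        raise ValueError(f"reference failed QC: {reference.qc.reasons}")
    if reference.concentration <= 0:
        raise ZeroDivisionError("reference concentration is zero")
    return target.concentration / reference.concentration


def read_well_table(path) -> list[DropletWell]:
    """Read a CSV well table (well, target, sample, accepted, positive,
    dilution, no_rt)."""
    df = pd.read_csv(path)
    required = {"well", "target", "sample", "accepted", "positive", "dilution", "no_rt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"well table missing column(s): {sorted(missing)}")
    return [
        DropletWell(
            well_id=str(r.well),
            target=str(r.target),
            accepted_droplets=int(r.accepted),
            positive_droplets=int(r.positive),
            dilution_factor=float(r.dilution),
            sample=str(r.sample),
            is_no_rt_control=bool(r.no_rt),
        )
        for r in df.itertuples()
    ]


def write_quantifications(quants: list[Quantification], path) -> None:
    rows = [
        {
            "sample": q.sample,
            "target": q.target,
            "lambda": q.lam,
            "copies_per_ul": q.concentration,
            "qc_pass": q.qc.passed,
            "reasons": ";".join(q.qc.reasons),
        }
        for q in quants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
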