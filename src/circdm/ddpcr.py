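"""Droplet digital PCR quantification of circular and linear templates.

A ddPCR reaction is partitioned into up to ~20,000 droplets; templates
distribute over droplets as a Poisson process, so the mean copies per
droplet is recovered from the fraction of negative droplets as
``lambda = -ln(negatives / total)``. Dilution-corrected circular (C) and
linear (L) template quantities give the fraction of circular particles

    FCP = C / (C + L)          (standard)
    FCP = C / L                (ratio mode, single-exon CDR1as-style assays)

Quality control follows two exclusion rules: (i) a sample is excluded for a
circRNA when its linear assay has fewer than 10 positive droplets; (ii) the
circRNA is dropped from a sample set when more than half of the samples
(controls and DM together) were excluded under rule (i).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import SampleMeta
from .diffexp import direction_bias_test, welch_t

#: QX200-style droplet volume in microlitres; FCP never depends on it.
DEFAULT_DROPLET_VOLUME_UL = 0.00085
DEFAULT_REACTION_VOLUME_UL = 20.0

MIN_LINEAR_POSITIVES = 10


class SaturationError(ValueError):
    """All droplets positive: the concentration is not estimable."""


@dataclass
class DropletRun:
    """One ddPCR well for one assay target."""

    well_id: str
    sample_id: str
    circ_id: str
    target: str  # "circular" or "linear"
    positives: int
    total: int
    dilution: float = 1.0

    def __post_init__(self) -> None:
        if self.target not in ("circular", "linear"):
            raise ValueError(f"target must be circular|linear, got {self.target!r}")
        if self.total < 1:
            raise ValueError("total droplets must be >= 1")
        if not 0 <= self.positives <= self.total:
            raise ValueError(f"positives {self.positives} out of [0, {self.total}]")
        if self.dilution <= 0:
            raise ValueError("dilution must be > 0")


def estimate_lambda(positives: int, total: int) -> float:
    """Poisson estimate of mean template copies per droplet."""
    if total < 1:
        raise ValueError("total droplets must be >= 1")
    if positives < 0 or positives > total:
        raise ValueError(f"positives {positives} out of [0, {total}]")
    if positives == total:
        raise SaturationError("all droplets positive; concentration not estimable")
    return -math.log((total - positives) / total)


def to_copies(
    lam: float,
    dilution: float = 1.0,
    droplet_volume_ul: float = DEFAULT_DROPLET_VOLUME_UL,
    reaction_volume_ul: float = DEFAULT_REACTION_VOLUME_UL,
) -> tuple[float, float]:
    """Convert copies per droplet to (copies per microlitre, copies per reaction)."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if droplet_volume_ul <= 0:
        raise ValueError("droplet volume must be > 0")
    per_ul = lam * dilution / droplet_volume_ul
    return per_ul, per_ul * reaction_volume_ul


def compute_fcp(C: float, L: float, mode: str = "standard") -> float:
    """Fraction of circular particles; NaN marks an undefined value."""
    if C < 0 or L < 0:
        raise ValueError("C and L must be >= 0")
    if mode == "standard":
        return C / (C + L) if C + L > 0 else math.nan
    if mode == "ratio":
        return C / L if L > 0 else math.nan
    raise ValueError(f"unknown FCP mode: {mode!r}")


@dataclass
class QuantResult:
    sample_id: str
    circ_id: str
    lambda_circ: float
    lambda_linear: float
    C: float  # dilution-corrected copies per reaction
    L: float
    fcp: float
    linear_positives: int
    excluded: bool = False
    exclusion_reason: str = ""


def quantify_runs(
    runs: Sequence[DropletRun],
    mode: str = "standard",
    droplet_volume_ul: float = DEFAULT_DROPLET_VOLUME_UL,
) -> list[QuantResult]:
    """Pair circular/linear wells per (sample, circRNA) and compute FCP."""
    by_key: dict[tuple[str, str], dict[str, DropletRun]] = {}
    for run in runs:
        slot = by_key.setdefault((run.sample_id, run.circ_id), {})
        if run.target in slot:
            raise ValueError(
                f"duplicate {run.target} well for sample {run.sample_id}, circ {run.circ_id}"
            )
        slot[run.target] = run
    out = []
    for (sid, cid), slot in by_key.items():
        if "circular" not in slot or "linear" not in slot:
            raise ValueError(f"sample {sid}, circ {cid}: need both circular and linear wells")
        rc, rl = slot["circular"], slot["linear"]
        lam_c = estimate_lambda(rc.positives, rc.total)
        lam_l = estimate_lambda(rl.positives, rl.total)
        _, C = to_copies(lam_c, rc.dilution, droplet_volume_ul)
        _, L = to_copies(lam_l, rl.dilution, droplet_volume_ul)
        out.append(
            QuantResult(
                sample_id=sid,
                circ_id=cid,
                lambda_circ=lam_c,
                lambda_linear=lam_l,
                C=C,
                L=L,
                fcp=compute_fcp(C, L, mode=mode),
                linear_positives=rl.positives,
            )
        )
    return out


def apply_exclusions(
    results: Sequence[QuantResult], min_linear_positives: int = MIN_LINEAR_POSITIVES
) -> tuple[list[QuantResult], list[str]]:
    """Apply rules (i) and (ii); returns flagged results and dropped circ ids.

    Rule (ii)'s "more than half" is strict: with 6 samples, 3 exclusions
    retain the circRNA, 4 drop it.
    """
    flagged = []
    for r in results:
        if r.linear_positives < min_linear_positives:
            flagged.append(
                QuantResult(
                    **{
                        **r.__dict__,
                        "excluded": True,
                        "exclusion_reason": (
                            f"linear positives {r.linear_positives} < {min_linear_positives}"
                        ),
                    }
                )
            )
        else:
            flagged.append(QuantResult(**r.__dict__))
    dropped = []
    by_circ: dict[str, list[QuantResult]] = {}
    for r in flagged:
        by_circ.setdefault(r.circ_id, []).append(r)
    for cid, rs in by_circ.items():
        n_excl = sum(r.excluded for r in rs)
        if n_excl > len(rs) / 2:
            dropped.append(cid)
            for r in rs:
                if not r.excluded:
                    r.excluded = True
                    r.exclusion_reason = "circRNA dropped: more than half of samples excluded"
                else:
                    r.exclusion_reason += "; circRNA dropped"
    return flagged, dropped


@dataclass
class PanelResult:
    """Per-circRNA group comparison plus the set-level direction-bias test."""

    table: pd.DataFrame  # circ_id, mean_control, mean_dm, sd_*, t, p, direction
    n_up: int
    n_down: int
    chi2: float
    chi2_p: float


def compare_panel(
    results: Sequence[QuantResult],
    meta: Sequence[SampleMeta],
    dropped: Sequence[str] = (),
) -> PanelResult:
    """Welch t-test on FCP per circRNA; chi-square on the up/down tally.

    Direction ties (zero mean difference) are excluded from the tally, as
    are circRNAs dropped by the exclusion rules.
    """
    group_of = {m.sample_id: m.group for m in meta}
    rows = []
    n_up = n_down = 0
    by_circ: dict[str, list[QuantResult]] = {}
    for r in results:
        if not r.excluded and not math.isnan(r.fcp):
            by_circ.setdefault(r.circ_id, []).append(r)
    for cid in sorted(by_circ):
        if cid in dropped:
            continue
        ctrl = [r.fcp for r in by_circ[cid] if group_of[r.sample_id] == "control"]
        dm = [r.fcp for r in by_circ[cid] if group_of[r.sample_id] == "DM"]
        if len(ctrl) < 2 or len(dm) < 2:
            continue
        t, df, p = welch_t(dm, ctrl)
        delta = float(np.mean(dm) - np.mean(ctrl))
        if delta > 0:
            direction = "up"
            n_up += 1
        elif delta < 0:
            direction = "down"
            n_down += 1
        else:
            direction = "tie"
        rows.append(
            {
                "circ_id": cid,
                "mean_control": float(np.mean(ctrl)),
                "mean_dm": float(np.mean(dm)),
                "sd_control": float(np.std(ctrl, ddof=1)),
                "sd_dm": float(np.std(dm, ddof=1)),
                "t": t,
                "p": p,
                "direction": direction,
            }
        )
    if n_up + n_down > 0:
        bias = direction_bias_test(n_up, n_down)
        chi2, chi2_p = bias.chi2, bias.p
    else:
        chi2, chi2_p = math.nan, math.nan
    return PanelResult(
        table=pd.DataFrame(rows), n_up=n_up, n_down=n_down, chi2=chi2, chi2_p=chi2_p
    )


# ---------------------------------------------------------------------------
# TSV interfaces


def read_droplet_tsv(path: str | Path) -> list[DropletRun]:
    df = pd.read_csv(path, sep="\t")
    return [
        DropletRun(
            well_id=str(r.well_id),
            sample_id=str(r.sample_id),
            circ_id=str(r.circ_id),
            target=str(r.target),
            positives=int(r.positives),
            total=int(r.total),
            dilution=float(r.dilution),
        )
        for r in df.itertuples()
    ]


def write_droplet_tsv(runs: Sequence[DropletRun], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in runs]).to_csv(path, sep="\t", index=False)


def write_quant_tsv(results: Sequence[QuantResult], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in results]).to_csv(path, sep="\t", index=False)
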