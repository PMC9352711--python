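"""Performance-evaluation statistics and the simulation harness.

Implements the arithmetic of analytical method validation as used for this
screening method: recovery and (relative) standard deviation of replicate
determinations, the five linearity statistics (intercept, slope, R, R^2,
RSS), the randomized factor layout for intermediate-precision designs, and
the one-sided 95%-confidence out-of-specification (OOS) detection limit.

OOS limit model
---------------
A single measurement of a sample whose true content is ``p`` is modelled as
normally distributed with standard deviation ``(RSD/100) * T`` where ``T``
is the specification threshold (default 90% of declared content).  The
largest true content for which a single measurement falls below ``T`` with
one-sided confidence ``c`` is then

    limit = T - z_c * (RSD / 100) * T

with ``z_c`` the standard-normal quantile.  This reproduces both published
limit values for this method (85.9% at RSD 2.79, 83.4% at RSD 4.46).

The simulation harness renders synthetic plates through the *full* image
pipeline, so the statistics above can be exercised end to end against known
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import synthetic
from .config import AnalysisConfig
from .errors import ValidationStatsError
from .plate import full_frame_quad
from .quantification import Annotations, ReferenceAnnotation, analyze_plate


# ---------------------------------------------------------------------------
# descriptive statistics

@dataclass
class RecoveryStats:
    n: int
    mean: float
    sd: float
    rsd: float       # 100 * sd / mean
    recovery: float  # 100 * mean / true content


def recovery_stats(replicates, true_content: float) -> RecoveryStats:
    """Mean, sample SD (n-1), RSD and recovery of replicate measurements."""
    x = np.asarray(replicates, float).ravel()
    if x.size < 2:
        raise ValidationStatsError(
            f"SD/RSD are undefined for fewer than 2 replicates (got {x.size})"
        )
    if true_content <= 0:
        raise ValidationStatsError("true content must be positive")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    return RecoveryStats(
        n=int(x.size),
        mean=mean,
        sd=sd,
        rsd=100.0 * sd / mean,
        recovery=100.0 * mean / true_content,
    )


@dataclass
class LinearityFit:
    intercept: float
    slope: float
    r: float
    r_squared: float
    rss: float
    n: int


def linearity_fit(true_contents, measured) -> LinearityFit:
    """OLS regression of measured on true content with the five reported
    statistics: intercept i, slope s, correlation R, determination R^2, and
    residual sum of squares RSS."""
    x = np.asarray(true_contents, float).ravel()
    y = np.asarray(measured, float).ravel()
    if x.size != y.size:
        raise ValidationStatsError("true and measured arrays differ in length")
    if np.unique(x).size < 3:
        raise ValidationStatsError(
            f"linearity requires at least 3 distinct content levels, got {np.unique(x).size}"
        )
    res = sps.linregress(x, y)
    fitted = res.slope * x + res.intercept
    rss = float(((y - fitted) ** 2).sum())
    return LinearityFit(
        intercept=float(res.intercept),
        slope=float(res.slope),
        r=float(res.rvalue),
        r_squared=float(res.rvalue**2),
        rss=rss,
        n=int(x.size),
    )


def oos_confidence_limit(
    rsd_percent: float,
    spec_threshold_percent: float = 90.0,
    confidence: float = 0.95,
) -> float:
    """Largest true content identifiable as OOS with the given one-sided
    confidence, from a single measurement with the given RSD.

    Strictly decreasing in RSD; equals the threshold at RSD 0.
    """
    if rsd_percent < 0:
        raise ValidationStatsError("RSD must be non-negative")
    if not 0 < confidence < 1:
        raise ValidationStatsError("confidence must lie in (0, 1)")
    z = float(sps.norm.ppf(confidence))
    t = float(spec_threshold_percent)
    return t - z * (rsd_percent / 100.0) * t


def precision_layout(
    seed: int,
    *,
    analytes: int | list[str] = 1,
    n_days: int = 2,
    n_photos: int = 3,
    n_investigators: int = 3,
    n_chosen: int = 6,
) -> pd.DataFrame:
    """Randomized factor combinations for the intermediate-precision design.

    For each analyte and each day, ``n_chosen`` of the ``n_photos x
    n_investigators`` combinations are drawn without replacement (default: 6
    of 9 on each of 2 days, i.e. 12 rows per analyte).
    """
    if n_chosen > n_photos * n_investigators:
        raise ValidationStatsError("cannot choose more combinations than exist")
    if isinstance(analytes, int):
        analytes = [f"A{i + 1:02d}" for i in range(analytes)]
    rng = np.random.default_rng(seed)
    combos = [(p, i) for p in range(1, n_photos + 1) for i in range(1, n_investigators + 1)]
    rows = []
    for analyte in analytes:
        for day in range(1, n_days + 1):
            for k in rng.choice(len(combos), size=n_chosen, replace=False):
                photo, investigator = combos[int(k)]
                rows.append(
                    {"analyte": analyte, "day": day, "photo": photo,
                     "investigator": investigator}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# simulation harness: synthetic scenes through the full image pipeline

def annotations_from_truth(
    truth: synthetic.GroundTruth,
    photo_width: int,
    photo_height: int,
    agent_name: str = "synthetic",
) -> Annotations:
    """Build the operator's annotation record from generator ground truth:
    reference spots are marked by their true coordinates with their known
    percentages, and the plate corners are entered explicitly."""
    refs = [
        ReferenceAnnotation(spot=(s.x, s.y), percentage=s.content)
        for s in truth.reference_spots()
    ]
    if truth.corners is not None:
        corners = np.asarray(truth.corners, float)
    else:
        corners = full_frame_quad(photo_width, photo_height).corners
    return Annotations(references=refs, agent_name=agent_name, corners=corners)


def run_scenario(
    spec: synthetic.PlateSpec,
    seed: int,
    config: AnalysisConfig | None = None,
    agent_name: str = "synthetic",
) -> pd.DataFrame:
    """Render one unwarped scene, analyse it, and pair estimates with truth.

    Returns one row per generator spot with columns ``role``, ``true`` and
    ``measured`` (the pipeline's percentage at the nearest detected spot).
    """
    if spec.warp is not None:
        raise ValidationStatsError(
            "run_scenario pairs truth with estimates in plate coordinates and "
            "therefore requires an unwarped scene"
        )
    config = config or AnalysisConfig()
    photo, truth = synthetic.render_plate(spec, seed)
    ann = annotations_from_truth(truth, photo.width, photo.height, agent_name)
    result = analyze_plate(photo, ann, config)

    rows = []
    for t in truth.spots:
        dists = [np.hypot(s.x - t.x, s.y - t.y) for s in result.spots]
        best = int(np.argmin(dists))
        if dists[best] > config.match_radius:
            raise ValidationStatsError(
                f"no detected spot within {config.match_radius:.0f} px of the true "
                f"{t.role} spot at ({t.x:.0f}, {t.y:.0f})"
            )
        rows.append(
            {
                "role": t.role,
                "true": t.content,
                "measured": result.spots[best].percentage,
                "x": t.x,
                "y": t.y,
            }
        )
    return pd.DataFrame(rows)


def simulate_repeatability(
    seed: int,
    *,
    n_analytes: int = 14,
    contents: tuple[float, ...] = (70.0, 85.0, 90.0),
    n_plates: int = 2,
    noise: dict | None = None,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Simulate the repeatability design through the image pipeline.

    For each analyte and content level, ``n_plates`` plates carrying two
    lanes of the test solution next to 60/80/100% reference lanes are
    rendered and analysed (default: 14 analytes x 3 contents x 4 replicate
    measurements).  Analytes differ in their darkening amplitude per percent
    (different APIs quench fluorescence to different degrees).

    Returns a tidy frame with columns analyte, content (true %), plate,
    lane, measured (%).
    """
    noise = synthetic.REPEATABILITY_NOISE if noise is None else noise
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(n_analytes):
        amp = 0.0020 + 0.0008 * (a / max(1, n_analytes - 1))
        analyte = f"A{a + 1:02d}"
        for content in contents:
            for p in range(n_plates):
                spec = synthetic.make_plate_spec(
                    (60.0, 80.0, 100.0),
                    (content, content),
                    amplitude_per_percent=amp,
                    noise_sigma=noise.get("noise_sigma", 0.0),
                    spot_amplitude_rsd=noise.get("spot_amplitude_rsd", 0.0),
                )
                plate_seed = int(rng.integers(0, 2**31 - 1))
                df = run_scenario(spec, plate_seed, config)
                samples = df[df["role"] == "sample"].reset_index(drop=True)
                for lane, row in samples.iterrows():
                    rows.append(
                        {
                            "analyte": analyte,
                            "content": content,
                            "plate": p,
                            "lane": lane,
                            "measured": row["measured"],
                        }
                    )
    return pd.DataFrame(rows)


def summarize_recovery(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per analyte-and-content recovery statistics of a simulation frame."""
    out = []
    for (analyte, content), grp in measurements.groupby(["analyte", "content"]):
        st = recovery_stats(grp["measured"].to_numpy(), float(content))
        out.append(
            {
                "analyte": analyte,
                "content": content,
                "n": st.n,
                "mean": st.mean,
                "sd": st.sd,
                "rsd": st.rsd,
                "recovery": st.recovery,
            }
        )
    return pd.DataFrame(out)


def pooled_recovery_rsd(measurements: pd.DataFrame) -> tuple[float, float]:
    """(mean recovery %, RSD of recoveries %) pooled over all measurements.

    Pooling across content levels uses recoveries (measured / true x 100),
    the convention under which measurements at different contents are
    commensurable.
    """
    rec = 100.0 * measurements["measured"] / measurements["content"]
    return float(rec.mean()), float(100.0 * rec.std(ddof=1) / rec.mean())
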