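"""Reference gating, cluster enrichment and cell-cycle group assignment.

Fluorescence provides the *reference* labels the label-free clustering is
evaluated against: aggregates (doublets) are excluded on a PI-width vs
PI-height band, the PI histogram's 2N and 4N windows separate G1 from G2/M,
and BrdU-FITC positivity marks S-phase cells (taking precedence over the
PI windows, since BrdU is the more specific S marker).

For each combined cluster c and phase p the *enrichment factor* is

    e(c, p) = f_c(p) / f_all(p),

the phase's frequency inside the cluster over its frequency among all
labeled singlets — the observed-over-expected reading of an enrichment
factor. It satisfies sum_p f_all(p) * e(c, p) = 1 per cluster. NOTE: this
definition is a documented convention of this package; thresholds for the
group assignment (t_specific, t_mixed) are likewise free parameters with
the defaults below.

Clusters are assigned to six groups: G1, predominantly G1 & S,
predominantly S & G1, predominantly S & G2/M, G2/M, and undefined, with
clusters under the size cutoff excluded. G1-G2/M is treated as
non-adjacent (no mixed group exists for that pair).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .cluster import CombinedClustering
from .errors import ContractError, GatingError
from .io import AcquisitionConfig

logger = logging.getLogger(__name__)

PHASES = ("G1", "S", "G2M")
GROUPS = ("G1", "G1&S", "S&G1", "S&G2M", "G2M", "undefined", "below_cutoff")


@dataclass
class GateConfig:
    """Reference-gate settings.

    ``singlet_n_sigma`` is the half-width (in robust SDs of the residual) of
    the accepted band around the fitted PI-W vs PI-H trend. PI windows are
    derived from the 2N peak of the PI histogram as mu +/- n_sigma*sigma and
    2*mu +/- n_sigma*(2*sigma) (the spread scales with the mean), unless
    given explicitly. The BrdU threshold is the valley between the modes of
    the log FITC-H histogram unless given.
    """

    singlet_n_sigma: float = 2.0
    pi_channel: str = "PI-A"
    pi_window_n_sigma: float = 2.0
    pi_2n_window: tuple | None = None
    pi_4n_window: tuple | None = None
    brdu_threshold: float | None = None
    min_ssc_height: float | None = None


def gate_singlets(events: pd.DataFrame, config: GateConfig = GateConfig()) -> pd.DataFrame:
    """Flag singlets on the PI-width vs PI-height plane.

    Fits a robust linear trend W ~ H (least squares after median centering,
    scaled by the residual MAD) and keeps events within
    ``singlet_n_sigma`` robust SDs of it; aggregates sit far above the band.
    Returns a copy with the ``singlet`` column set.
    """
    for col in ("PI-W", "PI-H"):
        if col not in events.columns:
            raise ContractError(f"events table lacks {col}")
    out = events.copy()
    h = out["PI-H"].to_numpy(dtype=np.float64)
    w = out["PI-W"].to_numpy(dtype=np.float64)
    # robust trend: fit on the half of events nearest the median width,
    # which excludes the aggregate tail from the fit itself
    med_w = np.median(w)
    mad0 = np.median(np.abs(w - med_w)) * 1.4826
    core = np.abs(w - med_w) <= max(3 * mad0, 1e-12)
    if core.sum() >= 2 and np.ptp(h[core]) > 0:
        slope, intercept = np.polyfit(h[core], w[core], 1)
    else:
        slope, intercept = 0.0, med_w
    resid = w - (slope * h + intercept)
    sd = np.median(np.abs(resid - np.median(resid))) * 1.4826
    sd = max(sd, 1e-9 * max(med_w, 1.0))
    singlet = np.abs(resid) <= config.singlet_n_sigma * sd
    if config.min_ssc_height is not None and "SSC-H" in out.columns:
        singlet &= out["SSC-H"].to_numpy() >= config.min_ssc_height
    out["singlet"] = singlet
    if singlet.mean() < 0.2:
        warnings.warn(f"only {singlet.mean():.0%} of events pass the singlet gate")
    return out


def _histogram_mode(values: np.ndarray, bins: int = 200) -> tuple[float, float]:
    """(mu, sigma) of the dominant histogram peak (robust sigma near the mode)."""
    counts, edges = np.histogram(values, bins=bins)
    smooth = gaussian_filter1d(counts.astype(float), 2.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mu = centers[int(np.argmax(smooth))]
    near = values[np.abs(values - mu) <= 0.2 * abs(mu)]
    if near.size < 5:
        raise GatingError("PI histogram peak too sparse to fit; supply manual windows")
    sigma = 1.4826 * np.median(np.abs(near - np.median(near)))
    return float(np.median(near)), float(max(sigma, 1e-9))


def _valley_threshold(values: np.ndarray, bins: int = 128) -> float:
    """Valley between the two largest modes of the log-intensity histogram."""
    logv = np.log10(np.clip(values, 1e-3, None))
    counts, edges = np.histogram(logv, bins=bins)
    smooth = gaussian_filter1d(counts.astype(float), 2.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    peaks, props = find_peaks(smooth, prominence=smooth.max() * 0.05)
    if len(peaks) < 2:
        raise GatingError("FITC histogram is not bimodal; supply brdu_threshold")
    top2 = peaks[np.argsort(smooth[peaks])[-2:]]
    lo, hi = sorted(top2)
    valley = lo + int(np.argmin(smooth[lo:hi + 1]))
    return float(10 ** centers[valley])


def gate_phases(events: pd.DataFrame, config: GateConfig = GateConfig()) -> pd.DataFrame:
    """Assign reference cell-cycle phases to gated singlets.

    S iff FITC-H exceeds the BrdU threshold; otherwise G1/G2M by the PI 2N
    and 4N windows; anything else (and every non-singlet) stays unlabeled.
    Windows and threshold are fitted from the singlet distributions when not
    supplied in the config.
    """
    if "singlet" not in events.columns:
        raise ContractError("run gate_singlets before gate_phases")
    out = events.copy()
    singlets = out["singlet"].to_numpy(dtype=bool)
    pi = out[config.pi_channel].to_numpy(dtype=np.float64)
    fitc = out["FITC-H"].to_numpy(dtype=np.float64)

    thr = config.brdu_threshold
    if thr is None:
        thr = _valley_threshold(fitc[singlets])
    if config.pi_2n_window is not None and config.pi_4n_window is not None:
        w2, w4 = tuple(config.pi_2n_window), tuple(config.pi_4n_window)
    else:
        # fit the 2N peak among BrdU-negative singlets (G1 dominates there)
        neg = singlets & (fitc <= thr)
        if neg.sum() < 20:
            raise GatingError("too few BrdU-negative singlets to fit PI windows")
        mu, sigma = _histogram_mode(pi[neg])
        ns = config.pi_window_n_sigma
        w2 = (mu - ns * sigma, mu + ns * sigma)
        w4 = (2 * mu - ns * 2 * sigma, 2 * mu + ns * 2 * sigma)
    if w2[1] >= w4[0]:
        raise GatingError(f"fitted PI windows overlap: 2N {w2}, 4N {w4}")

    phase = np.full(len(out), "unlabeled", dtype=object)
    is_s = singlets & (fitc > thr)
    is_g1 = singlets & ~is_s & (pi >= w2[0]) & (pi <= w2[1])
    is_g2m = singlets & ~is_s & (pi >= w4[0]) & (pi <= w4[1])
    phase[is_s] = "S"
    phase[is_g1] = "G1"
    phase[is_g2m] = "G2M"
    out["reference_phase"] = phase
    out.attrs["gate_fit"] = {"brdu_threshold": thr, "pi_2n_window": w2, "pi_4n_window": w4}
    return out


# ---------------------------------------------------------------------------
# Enrichment and group assignment


def enrichment_table(
    combined: CombinedClustering,
    events: pd.DataFrame,
    size_cutoff_fraction: float = 0.005,
) -> pd.DataFrame:
    """Per-combined-cluster phase fractions and enrichment factors.

    Fractions and enrichments are computed over labeled singlets; cluster
    sizes ``n`` count all events. Clusters smaller than
    ``size_cutoff_fraction`` of all events are flagged ``below_cutoff`` and
    excluded from group assignment. Phases absent from the whole sample get
    missing (NaN) enrichment, never infinity.
    """
    if len(events) != combined.n_events:
        raise ContractError("events table and clustering disagree in length")
    n_clusters = combined.k_a * combined.k_b
    ids = combined.combined_ids
    labeled = events["reference_phase"].isin(PHASES).to_numpy()
    if labeled.sum() == 0:
        raise ContractError("no labeled events; run the reference gates first")
    phase = events["reference_phase"].to_numpy()

    n_c = np.bincount(ids, minlength=n_clusters)
    rows = {"cluster": np.arange(n_clusters), "n": n_c}
    f_all = {}
    n_lab_total = labeled.sum()
    n_lab_c = np.bincount(ids[labeled], minlength=n_clusters)
    for p in PHASES:
        in_p = labeled & (phase == p)
        f_all[p] = in_p.sum() / n_lab_total
        count_cp = np.bincount(ids[in_p], minlength=n_clusters)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_c = np.where(n_lab_c > 0, count_cp / np.maximum(n_lab_c, 1), np.nan)
        rows[f"f_{p}"] = f_c
        rows[f"e_{p}"] = f_c / f_all[p] if f_all[p] > 0 else np.full(n_clusters, np.nan)
    table = pd.DataFrame(rows).set_index("cluster")
    table["below_cutoff"] = n_c < size_cutoff_fraction * combined.n_events
    table.attrs["f_all"] = f_all
    table.attrs["n_events"] = combined.n_events
    table.attrs["size_cutoff_fraction"] = size_cutoff_fraction
    return table


_ADJACENT = {frozenset({"G1", "S"}), frozenset({"S", "G2M"})}


def _group_for(e: dict[str, float], t_specific: float, t_mixed: float) -> str:
    if any(np.isnan(v) for v in e.values()):
        usable = {p: v for p, v in e.items() if not np.isnan(v)}
        if not usable:
            return "undefined"
        e = {p: e.get(p, -np.inf) if not np.isnan(e.get(p, np.nan)) else -np.inf
             for p in PHASES}
    order = sorted(PHASES, key=lambda p: -e[p])
    top, second = order[0], order[1]
    others = order[1:]
    if top in ("G1", "G2M") and e[top] >= t_specific and all(e[p] < t_mixed for p in others):
        return top
    if frozenset({top, second}) in _ADJACENT and e[top] >= t_mixed and e[second] >= t_mixed:
        if {top, second} == {"G1", "S"}:
            return f"{top}&{second}"
        return "S&G2M"  # the S-G2/M mixed group regardless of which leads
    return "undefined"


def assign_groups(table: pd.DataFrame, t_specific: float = 1.5,
                  t_mixed: float = 1.1) -> pd.DataFrame:
    """Assign each combined cluster to one of the six cell-cycle groups.

    A cluster is *pure* G1 or G2/M when that phase's enrichment reaches
    ``t_specific`` and both other enrichments stay below ``t_mixed``; it is
    a *mixed* group when its two top phases are cell-cycle-adjacent and both
    reach ``t_mixed`` (named leading-phase-first for G1-S); otherwise it is
    undefined. Below-cutoff clusters keep the ``below_cutoff`` group.
    """
    out = table.copy()
    groups = []
    for cid, row in out.iterrows():
        if row["below_cutoff"]:
            groups.append("below_cutoff")
            continue
        if row["n"] == 0:
            groups.append("below_cutoff")
            continue
        e = {p: row[f"e_{p}"] for p in PHASES}
        groups.append(_group_for(e, t_specific, t_mixed))
    out["group"] = groups
    out.attrs.update(table.attrs)
    out.attrs["t_specific"] = t_specific
    out.attrs["t_mixed"] = t_mixed
    return out


# ---------------------------------------------------------------------------
# Sample comparison (sorted aliquots) and arrest time course


@dataclass
class CompositionReport:
    """Cluster-group composition of a probe sample vs its reference."""

    group_fractions: pd.DataFrame      # rows: sample; columns: groups (sum to 1)
    fold_change: pd.Series             # per-cluster normalized size ratio probe/ref
    top_enriched: list[int]            # 3 clusters with highest fold change


def _group_fraction_row(combined: CombinedClustering, group_map: pd.Series) -> pd.Series:
    sizes = pd.Series(combined.sizes(), name="n")
    frac = sizes.groupby(group_map.reindex(sizes.index).fillna("undefined")).sum() \
        / max(combined.n_events, 1)
    return frac.reindex(list(GROUPS), fill_value=0.0)


def compare_samples(
    reference: CombinedClustering,
    probe: CombinedClustering,
    grouped_table: pd.DataFrame,
    n_top: int = 3,
) -> CompositionReport:
    """Compare a frozen-centroid-assigned probe against the reference sample.

    Both clusterings must come from the same frozen models (fingerprints are
    checked). Reports per-group composition of both samples, the per-cluster
    normalized fold change probe/reference, and the ``n_top`` most enriched
    clusters (among clusters populated in the reference).
    """
    for attr in ("fingerprint_a", "fingerprint_b"):
        fr, fp = getattr(reference, attr), getattr(probe, attr)
        if fr is not None and fp is not None and fr != fp:
            raise ContractError(
                f"model fingerprint mismatch on {attr}: probe was assigned with a "
                "different cluster model than the reference"
            )
    if "group" not in grouped_table.columns:
        raise ContractError("run assign_groups on the enrichment table first")
    group_map = grouped_table["group"]
    frac = pd.DataFrame({
        "reference": _group_fraction_row(reference, group_map),
        "probe": _group_fraction_row(probe, group_map),
    }).T
    ref_sizes = reference.sizes() / max(reference.n_events, 1)
    probe_sizes = probe.sizes() / max(probe.n_events, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(ref_sizes > 0, probe_sizes / ref_sizes, np.nan)
    fold = pd.Series(fc, name="fold_change")
    populated = fold.dropna()
    top = populated.sort_values(ascending=False).head(n_top).index.tolist()
    return CompositionReport(group_fractions=frac, fold_change=fold, top_enriched=top)


def assign_by_arrest(
    control_sizes: pd.Series | np.ndarray,
    arrested_sizes: pd.Series | np.ndarray,
    ratio_threshold: float = 1.2,
) -> pd.Series:
    """Label-free cluster assignment from a G2-arrest experiment.

    Clusters that grow by at least ``ratio_threshold`` in the sample taken
    immediately after release from the arrest (relative to the untreated
    control) are considered G2/M-specific; clusters that shrink by the
    reciprocal factor are G1 & S; everything else — including clusters empty
    in the control — stays unassigned. Sizes are fractions of each sample.
    """
    control = pd.Series(np.asarray(control_sizes, dtype=np.float64))
    arrested = pd.Series(np.asarray(arrested_sizes, dtype=np.float64))
    if len(control) != len(arrested):
        raise ContractError("control and arrested size vectors differ in length")
    out = pd.Series("unassigned", index=control.index, dtype=object)
    empty = control <= 0
    if empty.any():
        logger.info("%d clusters empty in control left unassigned", int(empty.sum()))
    ratio = arrested[~empty] / control[~empty]
    out.loc[ratio[ratio >= ratio_threshold].index] = "G2M"
    out.loc[ratio[ratio <= 1.0 / ratio_threshold].index] = "G1&S"
    return out


def arrest_composition(sizes_by_sample: dict[str, np.ndarray],
                       arrest_map: pd.Series) -> pd.DataFrame:
    """Per-sample fraction of events in G2M- vs G1&S-mapped clusters."""
    rows = {}
    g2m = arrest_map[arrest_map == "G2M"].index.to_numpy()
    g1s = arrest_map[arrest_map == "G1&S"].index.to_numpy()
    for name, sizes in sizes_by_sample.items():
        sizes = np.asarray(sizes, dtype=np.float64)
        total = sizes.sum()
        rows[name] = {
            "G2M": sizes[g2m].sum() / total if total else 0.0,
            "G1&S": sizes[g1s].sum() / total if total else 0.0,
        }
    return pd.DataFrame(rows).T
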