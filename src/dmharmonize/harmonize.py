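"""Distribution-matching harmonization of connectivity between sites.

For each connection, the transform T(c) = F_ref^{-1}(F_new(c)) maps a value
from the new site onto the value holding the same percentile at the reference
site, where both CDFs are fitted zero-inflated gamma mixtures.  Fitting and
mapping happen on log(1+c) by default (the log transform damps outliers and
stabilizes the gamma fit; zeros are invariant under log1p, so the zero
fraction lam is identical in either space), and the log is undone afterwards
with expm1.

Zeros always map to zeros: F_new(0) = 0 <= lam_ref, so the reference inverse
CDF returns 0.  When the reference site is sparser than the new site
(lam_ref > lam_new), small nonzero values whose percentile falls below
lam_ref also map to zero.  A non-zero-preserving variant (step u(0) = 1, so a
zero maps to the reference quantile at lam_new) is available behind the
``preserve_zeros=False`` flag but is off by default.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import ConnectivityTable, SubjectMetadata
from .zig import DEFAULT_MIN_NONZERO, P_CLIP, ZIGParams, fit_zig, zig_invcdf

__all__ = [
    "ConnectionTransform",
    "HarmonizationModel",
    "fit_harmonization",
    "apply_harmonization",
    "dm_transform",
    "residualize_covariate",
    "save_model",
    "load_model",
]

POOLED_STRATUM = "all"


@dataclass(frozen=True)
class ConnectionTransform:
    """One connection's fitted reference/new-site parameter pair."""

    ref_params: ZIGParams
    new_params: ZIGParams
    passthrough: bool


@dataclass
class HarmonizationModel:
    """Per-connection (per-stratum) quantile-mapping transform new -> reference."""

    reference_site: str
    new_site: str
    strata: list[str]
    # strata label -> list of ConnectionTransform, one per connection
    per_connection: dict[str, list[ConnectionTransform]]
    n_regions: int
    log_space: bool = True
    preserve_zeros: bool = True
    config: dict = field(default_factory=dict)

    @property
    def n_connections(self) -> int:
        return len(next(iter(self.per_connection.values())))

    def passthrough_manifest(self) -> list[tuple[str, int]]:
        """(stratum, connection index) pairs left unharmonized."""
        return [
            (stratum, k)
            for stratum, fits in self.per_connection.items()
            for k, tr in enumerate(fits)
            if tr.passthrough
        ]


def _single_site(meta: SubjectMetadata, table: ConnectivityTable, role: str) -> str:
    sites = meta.site_of(table.subject_ids).unique()
    if len(sites) != 1:
        raise ValueError(f"{role} table spans multiple sites: {sorted(sites)}")
    return str(sites[0])


def _strata_masks(
    table: ConnectivityTable, meta: SubjectMetadata, stratify_by_sex: bool
) -> dict[str, np.ndarray]:
    if not stratify_by_sex:
        return {POOLED_STRATUM: np.ones(table.n_subjects, dtype=bool)}
    sex = meta.sex_of(table.subject_ids)
    if sex.isna().any():
        missing = sex[sex.isna()].index.tolist()
        raise ValueError(f"sex missing for subjects {missing} under stratification")
    return {
        str(level): (sex == level).to_numpy()
        for level in sorted(sex.astype(str).unique())
    }


def fit_harmonization(
    ref: ConnectivityTable,
    new: ConnectivityTable,
    meta: SubjectMetadata,
    stratify_by_sex: bool = False,
    min_nonzero: int = DEFAULT_MIN_NONZERO,
    log_space: bool = True,
    preserve_zeros: bool = True,
) -> HarmonizationModel:
    """Fit the per-connection ZIG pairs defining the new-to-reference transform.

    Parameters are estimated independently for every connection at each site
    (and, when ``stratify_by_sex`` is set, within each sex group).  A
    connection is flagged passthrough — the identity map — when either site's
    gamma fit rests on fewer than ``min_nonzero`` positive values.
    """
    if ref.pair_index != new.pair_index:
        raise ValueError("reference and new tables must share pair_index")
    missing = [s for s in ref.subject_ids + new.subject_ids if s not in meta.frame.index]
    if missing:
        raise ValueError(f"subjects without metadata: {missing}")
    ref_site = _single_site(meta, ref, "reference")
    new_site = _single_site(meta, new, "new")

    ref_masks = _strata_masks(ref, meta, stratify_by_sex)
    new_masks = _strata_masks(new, meta, stratify_by_sex)
    absent = set(new_masks) - set(ref_masks)
    if absent:
        raise ValueError(
            f"strata {sorted(absent)} present in new site but absent in reference"
        )

    ref_vals = np.log1p(ref.values) if log_space else ref.values
    new_vals = np.log1p(new.values) if log_space else new.values

    per_connection: dict[str, list[ConnectionTransform]] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-connection shape<1 warnings are summarized
        for stratum, new_mask in new_masks.items():
            ref_mask = ref_masks[stratum]
            fits = []
            for k in range(ref.n_connections):
                rp = fit_zig(ref_vals[ref_mask, k], min_nonzero=min_nonzero)
                np_ = fit_zig(new_vals[new_mask, k], min_nonzero=min_nonzero)
                # all-zero on both sides is already the identity; only flag
                # passthrough when a needed gamma fit is untrustworthy
                degenerate_ok = rp.lam == 1.0 and np_.lam == 1.0
                passthrough = not degenerate_ok and not (rp.reliable and np_.reliable)
                fits.append(ConnectionTransform(rp, np_, passthrough))
            per_connection[stratum] = fits

    return HarmonizationModel(
        reference_site=ref_site,
        new_site=new_site,
        strata=sorted(new_masks),
        per_connection=per_connection,
        n_regions=ref.n_regions,
        log_space=log_space,
        preserve_zeros=preserve_zeros,
        config={"min_nonzero": min_nonzero, "stratify_by_sex": stratify_by_sex,
                "p_clip": P_CLIP},
    )


def dm_transform(
    values: np.ndarray,
    new_params: ZIGParams,
    ref_params: ZIGParams,
    preserve_zeros: bool = True,
) -> np.ndarray:
    """Quantile-map one connection's values from the new site to the reference.

    Applies F_ref^{-1}(F_new(c)) elementwise.  With ``preserve_zeros`` (the
    default), zeros have percentile 0 and stay zero; otherwise the step at
    zero uses u(0) = 1, so a zero is assigned percentile lam_new and may map
    to a positive reference quantile.
    """
    values = np.asarray(values, dtype=float)
    if ref_params.degenerate:
        # reference is a pure point mass: everything maps to zero
        return np.zeros_like(values)
    lam_n, lam_r = new_params.lam, ref_params.lam
    # Composing F_ref^{-1} with F_new at the mixture level loses precision
    # for values deep in the gamma lower tail (p - lam underflows), so the
    # inner probability is formed directly from the gamma CDF:
    #   (F_new(c) - lam_r) / (1 - lam_r)
    #     = (lam_n - lam_r)/(1 - lam_r) + q * (1 - lam_n)/(1 - lam_r)
    if new_params.degenerate:
        q = np.zeros_like(values)
    else:
        q = stats.gamma.cdf(values, new_params.gamma_shape, scale=new_params.beta)
    inner = (lam_n - lam_r) / (1.0 - lam_r) + q * (1.0 - lam_n) / (1.0 - lam_r)
    inner = np.minimum(inner, P_CLIP)
    out = np.where(
        inner > 0,
        stats.gamma.ppf(np.maximum(inner, 0.0), ref_params.gamma_shape,
                        scale=ref_params.beta),
        0.0,
    )
    if preserve_zeros:
        out = np.where(values == 0, 0.0, out)
    else:
        # step u(0) = 1: a zero carries percentile lam_new instead of 0
        p_zero = min(new_params.lam, P_CLIP)
        out_zero = (
            zig_invcdf(p_zero, ref_params) if p_zero > lam_r else 0.0
        )
        out = np.where(values == 0, out_zero, out)
    return out


def apply_harmonization(
    model: HarmonizationModel, new: ConnectivityTable, meta: SubjectMetadata
) -> ConnectivityTable:
    """Harmonize a new-site table onto the model's reference site.

    Values are mapped per connection and stratum as
    ``expm1( F_ref^{-1}( F_new( log1p(c) ) ) )`` (the log steps drop out when
    the model was fitted with ``log_space=False``).  Passthrough connections
    are copied unchanged.
    """
    n_conn_model = model.n_connections
    if new.n_connections != n_conn_model or new.n_regions != model.n_regions:
        raise ValueError("table shape does not match the fitted model")
    masks = _strata_masks(new, meta, model.config.get("stratify_by_sex", False))
    unknown = set(masks) - set(model.per_connection)
    if unknown:
        raise ValueError(f"subjects in strata {sorted(unknown)} absent from the model")

    vals = np.log1p(new.values) if model.log_space else new.values.copy()
    out = np.empty_like(vals)
    for stratum, mask in masks.items():
        fits = model.per_connection[stratum]
        for k in range(new.n_connections):
            tr = fits[k]
            col = vals[mask, k]
            if tr.passthrough:
                out[mask, k] = col
            else:
                out[mask, k] = dm_transform(
                    col, tr.new_params, tr.ref_params,
                    preserve_zeros=model.preserve_zeros,
                )
    result = np.expm1(out) if model.log_space else out
    # guard against -0.0 / tiny negative round-off from expm1
    np.clip(result, 0.0, None, out=result)
    return new.with_values(result)


def residualize_covariate(
    table: ConnectivityTable,
    meta: SubjectMetadata,
    covariate: str,
) -> tuple[ConnectivityTable, pd.DataFrame]:
    """Remove a linear covariate effect per connection, within each site.

    Fits the slope alpha of c on (x - x_bar) by least squares within each
    site and returns c_tilde = c - alpha (x - x_bar), together with the
    per-site, per-connection slopes so a caller can restore the effect after
    harmonization.  The covariate must be non-missing and non-constant within
    every site.
    """
    x = meta.covariate(covariate, table.subject_ids)
    if np.isnan(x).any():
        bad = [s for s, v in zip(table.subject_ids, x) if np.isnan(v)]
        raise ValueError(f"covariate {covariate!r} missing for subjects {bad}")
    sites = meta.site_of(table.subject_ids).to_numpy()
    values = table.values.copy()
    slopes = {}
    for site in np.unique(sites):
        mask = sites == site
        xc = x[mask] - x[mask].mean()
        ssx = float(xc @ xc)
        if ssx == 0.0:
            raise ValueError(f"covariate {covariate!r} is constant within site {site!r}")
        alpha = (xc @ values[mask]) / ssx  # closed-form OLS slope per connection
        values[mask] -= np.outer(xc, alpha)
        slopes[site] = alpha
    slope_frame = pd.DataFrame(slopes).T
    slope_frame.index.name = "site"
    # residuals can dip below zero; the table's non-negativity check is
    # bypassed so least-squares orthogonality holds exactly — the caller
    # decides whether to clip before harmonizing
    out = table.with_values(np.zeros_like(values))
    out.values = values
    return out, slope_frame


def _params_to_json(p: ZIGParams) -> dict:
    return p.to_dict()


def save_model(model: HarmonizationModel, path: str | Path) -> Path:
    """Persist a fitted model as JSON so fit and apply can run separately."""
    doc = {
        "reference_site": model.reference_site,
        "new_site": model.new_site,
        "strata": model.strata,
        "n_regions": model.n_regions,
        "log_space": model.log_space,
        "preserve_zeros": model.preserve_zeros,
        "config": model.config,
        "per_connection": {
            stratum: [
                {
                    "ref": _params_to_json(tr.ref_params),
                    "new": _params_to_json(tr.new_params),
                    "passthrough": tr.passthrough,
                }
                for tr in fits
            ]
            for stratum, fits in model.per_connection.items()
        },
    }
    path = Path(path)
    path.write_text(json.dumps(doc))
    return path


def load_model(path: str | Path) -> HarmonizationModel:
    doc = json.loads(Path(path).read_text())
    per_connection = {
        stratum: [
            ConnectionTransform(
                ref_params=ZIGParams.from_dict(e["ref"]),
                new_params=ZIGParams.from_dict(e["new"]),
                passthrough=e["passthrough"],
            )
            for e in fits
        ]
        for stratum, fits in doc["per_connection"].items()
    }
    return HarmonizationModel(
        reference_site=doc["reference_site"],
        new_site=doc["new_site"],
        strata=doc["strata"],
        per_connection=per_connection,
        n_regions=doc["n_regions"],
        log_space=doc["log_space"],
        preserve_zeros=doc["preserve_zeros"],
        config=doc["config"],
    )
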