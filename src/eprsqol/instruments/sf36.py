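"""SF-36 (version 1) scoring: eight 0-100 domains and norm-based summaries.

Item responses are integer codes (1..L per item) that are linearly recoded to
0-100 with 0 the lowest and 100 the highest perceived functioning; a domain
score is the mean of its recoded items (half-scale rule for missing items).
The physical and mental component summaries (PCS, MCS) standardize the eight
domains against reference means/SDs, combine the z-scores with factor-score
coefficients from a two-component orthogonal principal-factor solution, and
are reported as T-scores with mean 50 and SD 10 in the reference population.

Two sources of norms are supported: published US general-population (1990)
constants bundled with the package, or norms estimated from a user-supplied
norming sample (:meth:`Sf36Norms.from_sample`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DOMAINS = ["pf", "rp", "bp", "gh", "vt", "sf", "re", "mh"]
PHYSICAL_DOMAINS = ["pf", "rp", "bp", "gh"]

# Per-item recode tables: response code c (1-based) -> recoded 0-100 score.
_R3 = (0.0, 50.0, 100.0)
_R2 = (0.0, 100.0)
_R5_DESC = (100.0, 75.0, 50.0, 25.0, 0.0)
_R5_ASC = (0.0, 25.0, 50.0, 75.0, 100.0)
_R6_DESC = (100.0, 80.0, 60.0, 40.0, 20.0, 0.0)
_R6_ASC = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0)

# item number -> (domain, recode tuple); item 2 (health transition) is not
# part of any domain and is carried but never scored.
ITEM_TABLE: dict[int, tuple[str | None, tuple[float, ...]]] = {
    1: ("gh", _R5_DESC),
    2: (None, _R5_DESC),
    **{i: ("pf", _R3) for i in range(3, 13)},
    **{i: ("rp", _R2) for i in range(13, 17)},
    **{i: ("re", _R2) for i in range(17, 20)},
    20: ("sf", _R5_DESC),
    21: ("bp", _R6_DESC),
    22: ("bp", _R5_DESC),
    23: ("vt", _R6_DESC),
    24: ("mh", _R6_ASC),
    25: ("mh", _R6_ASC),
    26: ("mh", _R6_DESC),
    27: ("vt", _R6_DESC),
    28: ("mh", _R6_ASC),
    29: ("vt", _R6_ASC),
    30: ("mh", _R6_DESC),
    31: ("vt", _R6_ASC),
    32: ("sf", _R5_ASC),
    33: ("gh", _R5_ASC),
    34: ("gh", _R5_DESC),
    35: ("gh", _R5_ASC),
    36: ("gh", _R5_DESC),
}

N_ITEMS = 36

DOMAIN_ITEMS: dict[str, list[int]] = {
    d: [i for i, (dom, _) in ITEM_TABLE.items() if dom == d] for d in DOMAINS
}


def item_levels(item: int) -> int:
    return len(ITEM_TABLE[item][1])


def best_response(item: int) -> int:
    """Response code with the highest recoded score for this item."""
    rec = ITEM_TABLE[item][1]
    return int(np.argmax(rec)) + 1


def worst_response(item: int) -> int:
    rec = ITEM_TABLE[item][1]
    return int(np.argmin(rec)) + 1


def recode_items(items: pd.DataFrame) -> pd.DataFrame:
    """Map raw response codes (columns = 36 items in order) to 0-100 scores."""
    if items.shape[1] != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} SF-36 items, got {items.shape[1]}")
    out = np.full(items.shape, np.nan)
    raw = items.to_numpy(dtype=float)
    for j, item in enumerate(range(1, N_ITEMS + 1)):
        rec = np.asarray(ITEM_TABLE[item][1])
        col = raw[:, j]
        valid = ~np.isnan(col)
        codes = col[valid].astype(int)
        if ((codes < 1) | (codes > len(rec))).any():
            raise ValueError(f"item {item}: response code outside 1..{len(rec)}")
        out[valid, j] = rec[codes - 1]
    return pd.DataFrame(out, index=items.index, columns=items.columns)


def domain_scores(recoded: pd.DataFrame) -> pd.DataFrame:
    """Domain score = mean of recoded items; half-scale rule for missing.

    A domain is scored from the answered items when at least half of its
    items are answered, and is left missing (NaN) otherwise.
    """
    cols = list(recoded.columns)
    out = {}
    for d in DOMAINS:
        idx = [cols[i - 1] for i in DOMAIN_ITEMS[d]]
        block = recoded[idx]
        answered = block.notna().sum(axis=1)
        score = block.mean(axis=1)
        score[answered * 2 < len(idx)] = np.nan
        out[d] = score
    return pd.DataFrame(out, index=recoded.index)


def _varimax(loadings: np.ndarray, tol: float = 1e-10, max_iter: int = 500) -> np.ndarray:
    """Varimax rotation of a loading matrix (columns = factors)."""
    p, k = loadings.shape
    rot = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        lam = loadings @ rot
        u, s, vt = np.linalg.svd(
            loadings.T @ (lam**3 - (lam @ np.diag(np.sum(lam**2, axis=0))) / p)
        )
        rot = u @ vt
        new_var = np.sum(s)
        if var != 0 and new_var < var * (1 + tol):
            break
        var = new_var
    return loadings @ rot


@dataclass(frozen=True)
class Sf36Norms:
    """Reference means/SDs per domain and component factor-score coefficients.

    Coefficient vectors are scaled so that component scores have mean 0 and
    SD 1 in the reference population, hence T-scores 50 +/- 10.
    """

    means: pd.Series
    sds: pd.Series
    coef_pcs: pd.Series
    coef_mcs: pd.Series

    def __post_init__(self) -> None:
        for s in (self.means, self.sds, self.coef_pcs, self.coef_mcs):
            if list(s.index) != DOMAINS:
                raise ValueError(f"norms must be indexed by {DOMAINS}")
        if (self.sds <= 0).any():
            raise ValueError("reference SDs must be positive")
        if not self.coef_pcs.abs().sum() or not self.coef_mcs.abs().sum():
            raise ValueError("coefficient vectors must be nonzero")

    @classmethod
    def from_sample(cls, domains: pd.DataFrame) -> "Sf36Norms":
        """Estimate norms from a norming sample of domain scores.

        Domain means/SDs (ddof=1) standardize the sample; the factor-score
        coefficients come from a two-component principal-factor solution of
        the domain correlation matrix with varimax rotation (regression-method
        scores, rescaled to unit SD in the sample).  The component loading
        mostly on the physical domains is labelled PCS, the other MCS; signs
        are fixed so higher domain scores raise both components.
        """
        X = domains[DOMAINS].dropna()
        if len(X) < len(DOMAINS) + 2:
            raise ValueError("norming sample too small")
        means = X.mean()
        sds = X.std(ddof=1)
        if (sds <= 0).any():
            raise ValueError("constant domain in norming sample")
        Z = (X - means) / sds
        R = np.corrcoef(Z.to_numpy(), rowvar=False)
        vals, vecs = np.linalg.eigh(R)
        order = np.argsort(vals)[::-1][:2]
        load = vecs[:, order] * np.sqrt(vals[order])
        load = _varimax(load)
        # orient each factor positively, then label by physical-domain loading
        for j in range(2):
            if load[:, j].sum() < 0:
                load[:, j] *= -1
        phys_idx = [DOMAINS.index(d) for d in PHYSICAL_DOMAINS]
        phys_mass = np.abs(load[phys_idx, :]).sum(axis=0)
        p_col = int(np.argmax(phys_mass))
        m_col = 1 - p_col
        W = np.linalg.solve(R, load)
        scores = Z.to_numpy() @ W
        W = W / scores.std(axis=0, ddof=1)
        return cls(
            means=means,
            sds=sds,
            coef_pcs=pd.Series(W[:, p_col], index=DOMAINS),
            coef_mcs=pd.Series(W[:, m_col], index=DOMAINS),
        )

    @classmethod
    def us_1990(cls) -> "Sf36Norms":
        """Published US general-population (1990) constants bundled as data."""
        text = (
            resources.files("eprsqol.data").joinpath("sf36_us1990_norms.json").read_text()
        )
        return cls.from_dict(json.loads(text))

    @classmethod
    def from_dict(cls, d: Mapping) -> "Sf36Norms":
        return cls(
            means=pd.Series(d["means"]).reindex(DOMAINS),
            sds=pd.Series(d["sds"]).reindex(DOMAINS),
            coef_pcs=pd.Series(d["coef_pcs"]).reindex(DOMAINS),
            coef_mcs=pd.Series(d["coef_mcs"]).reindex(DOMAINS),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Sf36Norms":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "means": self.means.to_dict(),
                    "sds": self.sds.to_dict(),
                    "coef_pcs": self.coef_pcs.to_dict(),
                    "coef_mcs": self.coef_mcs.to_dict(),
                },
                indent=1,
            )
        )


@dataclass(frozen=True)
class Sf36Result:
    domains: pd.Series  # eight 0-100 domain scores
    pcs: float
    mcs: float


def components(domains: pd.DataFrame, norms: Sf36Norms) -> pd.DataFrame:
    """PCS/MCS T-scores from domain scores; missing domains propagate to NaN."""
    Z = (domains[DOMAINS] - norms.means) / norms.sds
    pcs = 50.0 + 10.0 * (Z @ norms.coef_pcs)
    mcs = 50.0 + 10.0 * (Z @ norms.coef_mcs)
    return pd.DataFrame({"pcs": pcs, "mcs": mcs}, index=domains.index)


def score_sf36_frame(items: pd.DataFrame, norms: Sf36Norms) -> pd.DataFrame:
    """Full scoring of a cohort: eight domains plus PCS and MCS per row."""
    dom = domain_scores(recode_items(items))
    comp = components(dom, norms)
    return pd.concat([dom, comp], axis=1)


def score_sf36(items: Sequence[float], norms: Sf36Norms) -> Sf36Result:
    """Score a single respondent's 36 coded responses."""
    frame = pd.DataFrame([list(items)], columns=[f"sf36_{i}" for i in range(1, 37)])
    scored = score_sf36_frame(frame, norms)
    row = scored.iloc[0]
    return Sf36Result(
        domains=row[DOMAINS].copy(), pcs=float(row["pcs"]), mcs=float(row["mcs"])
    )
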