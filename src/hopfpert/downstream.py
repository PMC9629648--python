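"""Network-level and node-hierarchy analyses of the perturbed model.

Covers the modulation of resting-state networks (Yeo-7 style labels)
under local sustained forcing, the per-node structural and functional
connectivity strengths (SCstrength and GBC), and the correlation of the
perturbative node hierarchy (PCI, susceptibility, information
capability) with regional heterogeneity maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, ranksums, spearmanr

from . import observables as obs
from .connectome import Parcellation
from .fitting import derive_seed
from .simulator import ForcingSpec, ModelParams, simulate

__all__ = [
    "RSNModulation",
    "rsn_modulation",
    "network_specificity",
    "strength_maps",
    "hierarchy_correlations",
    "within_network_fc",
]


@dataclass
class RSNModulation:
    """Within-network FC, perturbed vs unperturbed, per stimulated pair."""

    networks: list[str]
    pairs: list
    fc_perturbed: np.ndarray  # (n_pairs, n_networks) mean over sims
    fc_unperturbed: np.ndarray
    samples_perturbed: np.ndarray = field(repr=False, default=None)  # (pairs, nets, sims)
    samples_unperturbed: np.ndarray = field(repr=False, default=None)
    F0: float = 0.01

    @property
    def difference(self) -> np.ndarray:
        """Perturbed minus unperturbed within-network FC."""
        return self.fc_perturbed - self.fc_unperturbed

    def ranksum_tests(self) -> pd.DataFrame:
        """Per-network rank-sum test, perturbed vs unperturbed samples
        pooled over stimulated pairs and simulations."""
        rows = []
        for j, net in enumerate(self.networks):
            p_samp = self.samples_perturbed[:, j, :].ravel()
            u_samp = self.samples_unperturbed[:, j, :].ravel()
            stat, p = ranksums(p_samp, u_samp)
            rows.append({"network": net, "statistic": stat, "p_value": p})
        return pd.DataFrame(rows)


def within_network_fc(fc: np.ndarray, labels, networks=None) -> dict[str, float]:
    """Mean off-diagonal FC among each network's nodes.

    Networks with fewer than two nodes get NaN (no within pairs).
    """
    fc = np.asarray(fc, dtype=float)
    labels = np.asarray(labels)
    if networks is None:
        networks = sorted(set(labels.tolist()))
    out = {}
    for net in networks:
        idx = np.flatnonzero(labels == net)
        if idx.size < 2:
            out[net] = float("nan")
            continue
        sub = fc[np.ix_(idx, idx)]
        iu = np.triu_indices(idx.size, k=1)
        out[net] = float(sub[iu].mean())
    return out


def rsn_modulation(
    params: ModelParams,
    coupling,
    parc: Parcellation,
    pairs,
    F0: float = 0.01,
    n_sims: int = 10,
    seed: int = 0,
) -> RSNModulation:
    """Within-network FC change under sustained forcing of node pairs.

    For every stimulated homotopic pair, perturbed and unperturbed runs
    share seeds (paired design); the mean FC among each network's nodes
    is compared between the two. Every node must carry a network label.
    """
    if parc.network is None or any(not n for n in parc.network):
        raise ValueError("every node needs a resting-state-network label")
    labels = np.asarray(parc.network)
    networks = sorted(set(labels.tolist()))
    pairs = list(pairs)
    n_nets = len(networks)
    sp = np.empty((len(pairs), n_nets, n_sims))
    su = np.empty((len(pairs), n_nets, n_sims))
    for m, pair in enumerate(pairs):
        amp = np.zeros(params.n_nodes)
        amp[list(pair)] = F0
        forcing = ForcingSpec(F0=amp, schedule="sustained")
        for s in range(n_sims):
            sub_seed = derive_seed(seed, m, s)
            base = simulate(params, coupling, ForcingSpec(), seed=sub_seed)
            fc_u = obs.functional_connectivity(base.bold)
            if F0 > 0:
                run = simulate(params, coupling, forcing, seed=sub_seed)
                fc_p = obs.functional_connectivity(run.bold)
            else:
                fc_p = fc_u
            wp = within_network_fc(fc_p, labels, networks)
            wu = within_network_fc(fc_u, labels, networks)
            sp[m, :, s] = [wp[n] for n in networks]
            su[m, :, s] = [wu[n] for n in networks]
    return RSNModulation(
        networks=networks,
        pairs=pairs,
        fc_perturbed=sp.mean(axis=2),
        fc_unperturbed=su.mean(axis=2),
        samples_perturbed=sp,
        samples_unperturbed=su,
        F0=F0,
    )


def network_specificity(
    modulation: RSNModulation,
    pair_index: int,
    top_fraction: float = 0.15,
) -> pd.DataFrame:
    """Normalized per-network FC-difference profile for one stimulation.

    The perturbed-minus-unperturbed profile is rescaled by its maximum
    absolute value; ``in_top`` flags networks whose normalized response
    falls in the top ``top_fraction`` of the profile's range.
    """
    diff = modulation.difference[pair_index]
    scale = np.max(np.abs(diff))
    norm = diff / scale if scale > 0 else np.zeros_like(diff)
    lo, hi = norm.min(), norm.max()
    threshold = hi - top_fraction * (hi - lo) if hi > lo else hi
    return pd.DataFrame(
        {
            "network": modulation.networks,
            "difference": diff,
            "normalized": norm,
            "in_top": norm >= threshold,
        }
    )


def strength_maps(coupling, fc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Node-wise structural and functional connectivity strengths.

    SCstrength(n) = sum_p C_np; FCstrength (GBC) = sum_p FC_np with the
    unit diagonal excluded.
    """
    C = coupling.weights if hasattr(coupling, "weights") else np.asarray(coupling, float)
    fc = np.asarray(fc, dtype=float)
    sc_strength = C.sum(axis=1)
    fc_off = fc - np.diag(np.diag(fc))
    return sc_strength, fc_off.sum(axis=1)


def hierarchy_correlations(
    table: pd.DataFrame,
    target: str = "PCI",
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate a node-level perturbative measure with heterogeneity maps.

    ``table`` holds one row per node; every numeric column other than
    ``target`` is correlated against it. Columns with missing values are
    flagged and the correlation uses the complete rows only.
    """
    if target not in table.columns:
        raise ValueError(f"column {target!r} missing from hierarchy table")
    corr_fn = {"pearson": pearsonr, "spearman": spearmanr}[method]
    y = pd.to_numeric(table[target], errors="coerce")
    rows = []
    for col in table.columns:
        if col == target or not pd.api.types.is_numeric_dtype(table[col]):
            continue
        x = pd.to_numeric(table[col], errors="coerce")
        ok = x.notna() & y.notna()
        n = int(ok.sum())
        if n < 3:
            rows.append({"column": col, "r": np.nan, "p_value": np.nan,
                         "n": n, "incomplete": True})
            continue
        r, p = corr_fn(y[ok], x[ok])
        rows.append({"column": col, "r": float(r), "p_value": float(p),
                     "n": n, "incomplete": n < len(table)})
    return pd.DataFrame(rows)
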