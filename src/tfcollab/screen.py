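"""PC1 screening of subnetworks: summarise each subnetwork's member-TF
expression by its first principal component across samples and quantify
how well that eigenprofile tracks the members' mean expression, overall
and per tissue group.

Members are z-scored across samples (so each TF contributes equally),
samples are the observations, and PC1 is the projection of the samples
onto the first principal axis. The PC sign is arbitrary; every reported
diagnostic is sign-invariant, and exported scores are oriented so that
PC1 correlates non-negatively with the mean member z-profile.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .subnetworks import Subnetwork

logger = logging.getLogger(__name__)


@dataclass
class PCScreen:
    """Per-subnetwork PC1 diagnostics."""

    subnetwork_id: int
    pc1_scores: np.ndarray          # oriented: corr with mean member z-profile >= 0
    explained_variance_ratio: float
    concordance: float              # |Pearson r| between PC1 and mean member z-profile
    group_means: dict               # tissue group -> mean oriented PC1
    n_members_used: int = 0


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def subnetwork_pc1(X: ExpressionMatrix, subnet: Subnetwork) -> PCScreen:
    """Compute PC1 and concordance diagnostics for one subnetwork.

    Constant member profiles are excluded with a warning; fewer than two
    usable members is an error; at least three samples are required.
    """
    if X.n_samples < 3:
        raise ValueError("need at least 3 samples for PC1 screening")
    present = [t for t in subnet.member_tfs if t in set(X.gene_ids)]
    if len(present) < 2:
        raise ValueError(
            f"subnetwork {subnet.id}: fewer than 2 member TFs present in the matrix")
    M = X.values.loc[present].to_numpy(dtype=float)
    sd = M.std(axis=1)
    usable = sd > 0
    if not usable.all():
        dropped = [t for t, u in zip(present, usable) if not u]
        warnings.warn(
            f"subnetwork {subnet.id}: excluding constant member profile(s) {dropped}")
    M = M[usable]
    if M.shape[0] < 2:
        raise ValueError(f"subnetwork {subnet.id}: fewer than 2 usable (non-constant) members")
    Z = (M - M.mean(axis=1, keepdims=True)) / M.std(axis=1, keepdims=True)

    # samples as observations, members as variables
    D = Z.T                                  # n_samples x n_members, column-centered
    U, s, _ = np.linalg.svd(D, full_matrices=False)
    pc1 = U[:, 0] * s[0]
    evr = float(s[0] ** 2 / np.sum(s ** 2))

    mean_profile = Z.mean(axis=0)
    r = _pearson(pc1, mean_profile)
    if r < 0:                                # orientation convention
        pc1 = -pc1
        r = -r
    groups = np.asarray(X.groups_in_order())
    group_means = {g: float(pc1[groups == g].mean()) for g in X.group_order
                   if (groups == g).any()}
    return PCScreen(subnetwork_id=subnet.id, pc1_scores=pc1,
                    explained_variance_ratio=evr, concordance=abs(r),
                    group_means=group_means, n_members_used=int(M.shape[0]))


def screen_report(screens: list[PCScreen], groups: list | None = None) -> pd.DataFrame:
    """Ranking table: subnetworks sorted by concordance (descending),
    with explained-variance ratio and per-group oriented PC1 means."""
    if not screens:
        raise ValueError("no screens supplied")
    if groups is None:
        groups = list(screens[0].group_means)
    rows = []
    for sc in screens:
        row = {"subnetwork": sc.subnetwork_id,
               "n_members": sc.n_members_used,
               "explained_variance_ratio": sc.explained_variance_ratio,
               "concordance": sc.concordance}
        for g in groups:
            row[f"pc1_mean_{g}"] = sc.group_means.get(g, np.nan)
        rows.append(row)
    df = pd.DataFrame(rows).sort_values(
        ["concordance", "subnetwork"], ascending=[False, True])
    return df.reset_index(drop=True)


def pc1_to_tsv(screens: list[PCScreen], X: ExpressionMatrix, path) -> None:
    data = {"sample": X.sample_ids, "group": X.groups_in_order()}
    for sc in screens:
        data[f"pc1_subnet{sc.subnetwork_id}"] = sc.pc1_scores
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.10g")


def plot_screen(X: ExpressionMatrix, subnet: Subnetwork, screen: PCScreen, path) -> None:
    """Member expression curves (z-scored, green) with oriented PC1 (red)
    across samples, tissue groups separated by dashed verticals."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    present = [t for t in subnet.member_tfs if t in set(X.gene_ids)]
    M = X.values.loc[present].to_numpy(dtype=float)
    sd = M.std(axis=1, keepdims=True)
    Z = np.where(sd > 0, (M - M.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1), 0)
    fig, ax = plt.subplots(figsize=(10, 4))
    xs = np.arange(X.n_samples)
    for row in Z:
        ax.plot(xs, row, color="green", alpha=0.3, lw=0.8)
    pc = screen.pc1_scores
    ax.plot(xs, pc / max(np.abs(pc).max(), 1e-12) * max(np.abs(Z).max(), 1),
            color="red", lw=2, label="PC1 (scaled)")
    groups = X.groups_in_order()
    for i in range(1, len(groups)):
        if groups[i] != groups[i - 1]:
            ax.axvline(i - 0.5, color="blue", ls="--", lw=0.8)
    ax.set_xlabel("sample (tissue-group order)")
    ax.set_ylabel("z-scored expression")
    ax.set_title(f"Subnetwork {subnet.id}: concordance "
                 f"{screen.concordance:.3f}, EVR {screen.explained_variance_ratio:.3f}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
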