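"""Incompleteness-aware core/accessory partitioning of a pangenome.

Draft genomes (MAGs, SAGs) are incomplete, so a gene absent from some
members of a species cluster may still belong to the species core: the
absence can simply reflect the genome's incompleteness.  This module
decides, per gene cluster, which explanation is more likely.

Model
-----
For a mOTU with genomes :math:`i = 1..N` of completeness :math:`c_i`
(fraction of the genome recovered), a gene's observed presence/absence
profile :math:`x \\in \\{0,1\\}^N` is scored under two Bernoulli-product
hypotheses:

* **core** — the gene is in every genome; genome *i* shows it with
  probability :math:`c_i`:

  .. math:: \\log L_{core} = \\sum_{i: x_i=1} \\ln c_i + \\sum_{i: x_i=0} \\ln (1-c_i)

* **accessory** — the gene is carried sporadically; genome *i* shows it
  with its accessory carriage probability :math:`p_i`, the fraction of
  the mOTU's distinct accessory gene clusters observed in genome *i*:

  .. math:: \\log L_{acc} = \\sum_{i: x_i=1} \\ln p_i + \\sum_{i: x_i=0} \\ln (1-p_i)

A gene is core exactly when :math:`\\log L_{core} > \\log L_{acc}`.
Because :math:`p_i` depends on which genes are currently accessory, the
assignment is iterated to a fixed point, starting from the genes whose
observed frequency is at least the mean completeness.  All probabilities
are clamped to [1e-3, 0.999] so log-likelihoods stay finite.

This is a reconstruction of the published one-sentence decision rule
(presence-absence profile more probable assuming the gene is in every
genome, considering incompleteness, than the converse); no equivalence
with any particular pangenome software is claimed.  Contamination is not
modelled: with contamination capped at 5% its effect is second-order.

Usage follows the model/results idiom::

    model = CorePangenomeModel.from_dataframe(presence_df, completeness)
    results = model.fit()
    print(results.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CorePangenomeModel",
    "GenePartitionResults",
    "loglik_core",
    "loglik_accessory",
    "summarize_partitions",
]

#: clamping constant for completeness and carriage probabilities
EPS = 1e-3
_CLAMP_LO, _CLAMP_HI = EPS, 1.0 - EPS


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(p, _CLAMP_LO, _CLAMP_HI)


def loglik_core(presence_row: Sequence[int], completeness: Sequence[float]) -> float:
    """Log-probability of a presence profile if the gene is in every genome.

    Present genomes contribute ln(c_i), absent genomes ln(1 - c_i), with
    completeness clamped to [1e-3, 0.999].
    """
    x = np.asarray(presence_row, dtype=float)
    c = _clamp(np.asarray(completeness, dtype=float))
    if x.shape != c.shape:
        raise ValueError(f"length mismatch: profile {x.shape} vs completeness {c.shape}")
    return float(x @ np.log(c) + (1.0 - x) @ np.log1p(-c))


def loglik_accessory(presence_row: Sequence[int], carriage_prob: Sequence[float]) -> float:
    """Log-probability of a presence profile under sporadic carriage.

    Genome *i* carries the gene with probability p_i (its observed
    accessory-gene fraction), clamped to [1e-3, 0.999].
    """
    x = np.asarray(presence_row, dtype=float)
    p = _clamp(np.asarray(carriage_prob, dtype=float))
    if x.shape != p.shape:
        raise ValueError(f"length mismatch: profile {x.shape} vs carriage {p.shape}")
    return float(x @ np.log(p) + (1.0 - x) @ np.log1p(-p))


class CorePangenomeModel:
    """Core/accessory classifier for one mOTU's gene presence matrix.

    Parameters
    ----------
    presence : pandas.DataFrame
        0/1 matrix, rows = gene clusters, columns = genome ids.  Rows
        observed in no genome are invalid (an unobserved gene carries no
        evidence and is reported "absent" upstream, never classified).
    completeness : mapping
        genome_id → completeness as a fraction in (0, 1] (values given
        as percent >1 are converted).
    """

    def __init__(self, presence: pd.DataFrame, completeness: Mapping[str, float]):
        if presence.shape[1] < 1:
            raise ValueError("presence matrix needs at least one genome")
        vals = presence.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("presence matrix cells must be 0/1")
        if presence.shape[0] and (vals.sum(axis=1) == 0).any():
            bad = presence.index[vals.sum(axis=1) == 0].tolist()
            raise ValueError(f"all-zero gene rows are undefined: {bad[:5]}")
        missing = [g for g in presence.columns if g not in completeness]
        if missing:
            raise ValueError(f"no completeness for genomes: {missing[:5]}")
        c = np.array([float(completeness[g]) for g in presence.columns])
        if (c > 1.0).any():  # given as percent
            c = c / 100.0
        if (c <= 0).any() or (c > 1.0).any():
            raise ValueError("completeness must be in (0, 1] (or percent (0, 100])")
        self.presence = presence.astype(np.int8)
        self.genomes = list(presence.columns)
        self.genes = list(presence.index)
        self.completeness = _clamp(c)

    @classmethod
    def from_dataframe(
        cls, presence: pd.DataFrame, completeness: Mapping[str, float]
    ) -> "CorePangenomeModel":
        """Build from a genes × genomes 0/1 DataFrame (drops unobserved rows)."""
        observed = presence.loc[presence.sum(axis=1) > 0]
        return cls(observed, completeness)

    def fit(
        self, max_iter: int = 100, reestimate_completeness: bool = False
    ) -> "GenePartitionResults":
        """Iterate the likelihood comparison to a fixed point.

        Starts from core = genes with observed frequency ≥ mean
        completeness, recomputes the carriage probabilities from the
        current accessory set, reassigns every gene, and repeats until
        the assignment stops changing or ``max_iter`` is reached.  If the
        assignment cycles, the lexicographically smallest assignment in
        the cycle is returned with ``converged=False``.  With
        ``reestimate_completeness`` the completeness vector is re-derived
        after each pass as the fraction of current core genes each genome
        shows.
        """
        X = self.presence.to_numpy(dtype=float)
        n_genes, n_genomes = X.shape
        c = self.completeness.copy()
        if n_genes == 0:
            return GenePartitionResults(
                model=self, core_mask=np.zeros(0, dtype=bool),
                ll_core=np.zeros(0), ll_acc=np.zeros(0),
                carriage=np.full(n_genomes, _CLAMP_LO),
                n_iterations=0, converged=True,
                posterior_completeness=c if reestimate_completeness else None,
            )
        order = np.argsort(np.asarray(self.genes, dtype=object))  # label order, for cycle ties

        def reestimated_c(mask: np.ndarray) -> np.ndarray:
            n_core = int(mask.sum())
            if n_core == 0:
                return self.completeness.copy()
            return _clamp(X[mask].sum(axis=0) / n_core)

        def step(mask: np.ndarray, c_vec: np.ndarray):
            p = self._carriage(X, mask)
            llc = X @ np.log(c_vec) + (1.0 - X) @ np.log1p(-c_vec)
            lla = X @ np.log(p) + (1.0 - X) @ np.log1p(-p)
            return llc > lla, llc, lla, p

        freq = X.mean(axis=1)
        core = freq >= c.mean()
        seen: dict[bytes, int] = {core.tobytes(): 0}
        history = [core]
        converged = False
        n_iter = 0
        llc = lla = p = None
        for n_iter in range(1, max_iter + 1):
            new_core, llc, lla, p = step(core, c)
            if np.array_equal(new_core, core):
                converged = True
                break
            key = new_core.tobytes()
            if key in seen:
                # oscillation: return the lexicographically smallest state in
                # the cycle, with the likelihoods its predecessor produced so
                # that assignment == (ll_core > ll_acc) still holds
                cycle = history[seen[key]:]
                idx = min(range(len(cycle)), key=lambda i: tuple(cycle[i][order]))
                pred = cycle[idx - 1]  # cycle[0]'s predecessor is the last state
                c_pred = reestimated_c(pred) if reestimate_completeness else c
                core, llc, lla, p = step(pred, c_pred)
                if reestimate_completeness:
                    c = reestimated_c(core)
                break
            seen[key] = len(history)
            history.append(new_core)
            core = new_core
            if reestimate_completeness:
                c = reestimated_c(core)
        return GenePartitionResults(
            model=self, core_mask=core, ll_core=llc, ll_acc=lla, carriage=p,
            n_iterations=n_iter, converged=converged,
            posterior_completeness=c if reestimate_completeness else None,
        )

    @staticmethod
    def _carriage(X: np.ndarray, core: np.ndarray) -> np.ndarray:
        """Per-genome accessory carriage: observed accessory genes / pool size."""
        acc = ~core
        pool = int(acc.sum())
        if pool == 0:
            return np.full(X.shape[1], _CLAMP_LO)
        return _clamp(X[acc].sum(axis=0) / pool)


@dataclass
class GenePartitionResults:
    """Fitted core/accessory partition for one mOTU."""

    model: CorePangenomeModel
    core_mask: np.ndarray
    ll_core: np.ndarray
    ll_acc: np.ndarray
    carriage: np.ndarray
    n_iterations: int
    converged: bool
    posterior_completeness: np.ndarray | None = None

    @property
    def assignment(self) -> pd.Series:
        """gene → 'core' / 'accessory'."""
        return pd.Series(
            np.where(self.core_mask, "core", "accessory"),
            index=self.model.genes, name="assignment",
        )

    @property
    def core_genes(self) -> list[str]:
        return [g for g, is_core in zip(self.model.genes, self.core_mask) if is_core]

    @property
    def accessory_genes(self) -> list[str]:
        return [g for g, is_core in zip(self.model.genes, self.core_mask) if not is_core]

    def classify_profile(self, profile: Mapping[str, int] | Sequence[int]) -> tuple[str, float, float]:
        """Classify a new presence profile with the fitted parameters.

        Returns (assignment, loglik_core, loglik_accessory).  Used to
        place marker genes on the fitted core/accessory scale without
        refitting.
        """
        if isinstance(profile, Mapping):
            row = [int(profile.get(g, 0)) for g in self.model.genomes]
        else:
            row = list(profile)
        c = self.posterior_completeness if self.posterior_completeness is not None \
            else self.model.completeness
        llc = loglik_core(row, c)
        lla = loglik_accessory(row, self.carriage)
        return ("core" if llc > lla else "accessory", llc, lla)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.model.genes,
                "assignment": self.assignment.to_numpy(),
                "loglik_core": self.ll_core,
                "loglik_accessory": self.ll_acc,
            }
        )

    def summary(self) -> str:
        n_core = int(self.core_mask.sum())
        n_acc = int((~self.core_mask).sum())
        c = self.posterior_completeness if self.posterior_completeness is not None \
            else self.model.completeness
        lines = [
            "Core/accessory pangenome partition",
            "==================================",
            f"genomes:               {len(self.model.genomes)}",
            f"gene clusters:         {len(self.model.genes)}",
            f"core genes:            {n_core}",
            f"accessory genes:       {n_acc}",
            f"mean completeness:     {float(np.mean(c)):.3f}",
            f"mean carriage prob:    {float(np.mean(self.carriage)):.3f}",
            f"iterations:            {self.n_iterations}",
            f"converged:             {self.converged}",
        ]
        return "\n".join(lines)


def fit_motu_partitions(
    presence: pd.DataFrame,
    completeness: Mapping[str, float],
    motus: Mapping[str, Sequence[str]],
    max_iter: int = 100,
    reestimate_completeness: bool = False,
) -> dict[str, GenePartitionResults]:
    """Fit a core/accessory partition per mOTU from a combined presence matrix.

    ``presence`` spans all genomes (genes × genomes); for each mOTU the
    member columns are taken and genes unobserved in that mOTU are
    dropped (they are "absent", not classifiable).  Members without a
    presence column are skipped with a warning.
    """
    import warnings

    out: dict[str, GenePartitionResults] = {}
    for motu_id in sorted(motus):
        members = [g for g in motus[motu_id] if g in presence.columns]
        skipped = sorted(set(motus[motu_id]) - set(members))
        if skipped:
            warnings.warn(
                f"{motu_id}: no gene presence column for {skipped[:3]}; skipped",
                stacklevel=2,
            )
        if not members:
            continue
        sub = presence[members]
        model = CorePangenomeModel.from_dataframe(sub, completeness)
        out[motu_id] = model.fit(max_iter=max_iter, reestimate_completeness=reestimate_completeness)
    return out


def summarize_partitions(results: Mapping[str, GenePartitionResults]) -> pd.DataFrame:
    """Per-mOTU summary table: core size, accessory size, completeness."""
    rows = []
    for motu_id in sorted(results):
        res = results[motu_id]
        c = res.posterior_completeness if res.posterior_completeness is not None \
            else res.model.completeness
        rows.append(
            {
                "motu_id": motu_id,
                "n_genomes": len(res.model.genomes),
                "n_core": int(res.core_mask.sum()),
                "n_accessory": int((~res.core_mask).sum()),
                "mean_completeness": float(np.mean(c)),
                "converged": res.converged,
                "n_iterations": res.n_iterations,
            }
        )
    return pd.DataFrame(rows)
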