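"""File formats, run manifests and test-fixture generation.

All tables are UTF-8 comma-separated with a header row; trees are
Newick with branch lengths. The fixture bundle writes the tiny
deterministic inputs used across the test suite together with expected
values computed by independent brute-force oracles (path-sum cophenetic
distances, a naive UPGMA, hand-normalized incidence products).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assembly import CommunityMatrix
from .betadiv import BetaMatrix
from .errors import SchemaError
from .evolution import Phylogeny, SpeciesPool
from .gridinfer import RESPONSES, ProcessSurface
from .landscape import Landscape, write_sites_csv

__all__ = [
    "write_community_csv",
    "read_community_csv",
    "write_species_pool_csv",
    "read_species_pool_csv",
    "write_beta_csv",
    "write_fractions_csv",
    "write_surface_csv",
    "read_surface_csv",
    "write_manifest",
    "read_traits_csv",
    "make_fixtures",
]


# ---------------------------------------------------------------------------
# Community matrices


def write_community_csv(comm: CommunityMatrix, path, long: bool = False) -> None:
    if long:
        rows = []
        for k, site in enumerate(comm.site_ids):
            for j, sp in enumerate(comm.species_ids):
                if comm.counts[k, j]:
                    rows.append((site, sp, int(comm.counts[k, j])))
        pd.DataFrame(rows, columns=["site_id", "species_id", "count"]).to_csv(
            path, index=False
        )
        return
    df = pd.DataFrame(comm.counts, columns=comm.species_ids)
    df.insert(0, "site_id", comm.site_ids)
    df.to_csv(path, index=False)


def read_community_csv(path) -> CommunityMatrix:
    df = pd.read_csv(path)
    if "site_id" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'site_id'")
    if {"species_id", "count"}.issubset(df.columns):  # long format
        wide = df.pivot_table(
            index="site_id", columns="species_id", values="count", fill_value=0
        )
        counts = wide.to_numpy()
        site_ids = [str(s) for s in wide.index]
        species = [str(s) for s in wide.columns]
    else:
        species = [c for c in df.columns if c != "site_id"]
        counts = df[species].to_numpy()
        site_ids = [str(s) for s in df["site_id"]]
    if np.isnan(counts.astype(float)).any():
        raise SchemaError(f"{path}: missing count values")
    totals = counts.sum(axis=1)
    if len(set(totals.tolist())) != 1:
        raise SchemaError(
            f"{path}: unequal row totals {sorted(set(totals.tolist()))}; "
            "the fixed-J pipeline expects equal community abundance"
        )
    return CommunityMatrix(
        counts=counts.astype(np.int64),
        site_ids=site_ids,
        species_ids=species,
        J=int(totals[0]),
    )


# ---------------------------------------------------------------------------
# Species pool tables


def write_species_pool_csv(pool: SpeciesPool, path) -> None:
    cols: dict[str, object] = {"species_id": pool.species_ids}
    for i in range(pool.T.shape[1]):
        cols[f"T{i + 1}"] = pool.T[:, i]
    for j in range(pool.R.shape[1]):
        cols[f"R{j + 1}"] = pool.R[:, j]
    if pool.F is not None:
        cols["F"] = pool.F
    pd.DataFrame(cols).to_csv(path, index=False)


def read_species_pool_csv(path, tree: Phylogeny) -> SpeciesPool:
    df = pd.read_csv(path)
    if "species_id" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'species_id'")
    df = df.set_index("species_id")
    try:
        df = df.loc[tree.tip_labels]
    except KeyError as exc:
        raise SchemaError(f"{path}: species missing for tree tips: {exc.args[0]}")
    t_cols = sorted((c for c in df.columns if c.startswith("T")), key=lambda c: c[1:])
    r_cols = sorted((c for c in df.columns if c.startswith("R")), key=lambda c: c[1:])
    F = df["F"].to_numpy() if "F" in df.columns else None
    return SpeciesPool(
        phylogeny=tree,
        T=df[t_cols].to_numpy(),
        R=df[r_cols].to_numpy(),
        F=F,
        species_ids=list(tree.tip_labels),
    )


def read_traits_csv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path)
    if "species_id" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'species_id'")
    ids = [str(s) for s in df["species_id"]]
    T = df.drop(columns=["species_id"]).to_numpy(dtype=float)
    if np.isnan(T).any():
        raise SchemaError(f"{path}: missing trait values")
    return T, ids


# ---------------------------------------------------------------------------
# Beta matrices, fractions, surfaces


def write_beta_csv(betas: dict[str, BetaMatrix] | list[BetaMatrix], path) -> None:
    """Long format: site_a, site_b, metric, value, orientation."""
    if isinstance(betas, dict):
        betas = list(betas.values())
    rows = []
    for bm in betas:
        n = len(bm.site_ids)
        for a in range(n):
            for b in range(a + 1, n):
                rows.append(
                    (bm.site_ids[a], bm.site_ids[b], bm.metric,
                     bm.values[a, b], bm.orientation)
                )
    pd.DataFrame(
        rows, columns=["site_a", "site_b", "metric", "value", "orientation"]
    ).to_csv(path, index=False)


def write_fractions_csv(rows: list[dict], path) -> None:
    cols = ["metric", "env_only", "space_only", "shared", "residual",
            "spatial_slope", "environmental_slope"]
    pd.DataFrame(rows)[cols].to_csv(path, index=False)


def write_surface_csv(surface: ProcessSurface, path) -> None:
    """Long format: n, d, metric, component, mean, std, replicates."""
    rows = []
    for (n, d, metric), row in surface.means.iterrows():
        for comp in RESPONSES:
            sd = (
                surface.stds.loc[(n, d, metric), comp]
                if surface.stds is not None
                else np.nan
            )
            rows.append((n, d, metric, comp, row[comp], sd, int(row["completed"])))
    pd.DataFrame(
        rows, columns=["n", "d", "metric", "component", "mean", "std", "replicates"]
    ).to_csv(path, index=False)


def read_surface_csv(path) -> ProcessSurface:
    df = pd.read_csv(path)
    need = {"n", "d", "metric", "component", "mean"}
    if df.empty or not need.issubset(df.columns):
        raise SchemaError(
            f"{path}: surface file needs non-empty columns {sorted(need)}"
        )
    wide = df.pivot_table(
        index=["n", "d", "metric"], columns="component", values="mean"
    )
    wide["completed"] = (
        df.pivot_table(index=["n", "d", "metric"], columns="component",
                       values="replicates").iloc[:, 0]
        if "replicates" in df.columns
        else 0
    )
    stds = None
    if "std" in df.columns:
        stds = df.pivot_table(
            index=["n", "d", "metric"], columns="component", values="std"
        )
    n_values = np.sort(df["n"].unique())
    d_values = np.sort(df["d"].unique())
    return ProcessSurface(
        means=wide,
        records=pd.DataFrame(),
        n_values=n_values,
        d_values=d_values,
        replicates=int(wide["completed"].max()) if len(wide) else 0,
        valid=np.ones((len(n_values), len(d_values)), dtype=bool),
        stds=stds,
    )


def write_manifest(path, config_dict: dict, seed: int, config_hash: str,
                   extra: dict | None = None) -> None:
    manifest = {
        "package": "betaproc",
        "version": __version__,
        "config_hash": config_hash,
        "master_seed": seed,
        "config": config_dict,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))


# ---------------------------------------------------------------------------
# Fixture bundle with independent oracles


def _oracle_cophenetic(newick_edges: dict, tips: list[str]) -> dict:
    """Brute-force path-sum distances on an explicit edge dict
    {child: (parent, length)} by walking both tips to the root."""

    def path_to_root(t):
        out = []
        while t in newick_edges:
            parent, length = newick_edges[t]
            out.append((t, length))
            t = parent
        return out, t

    result = {}
    for i, a in enumerate(tips):
        for b in tips[i + 1:]:
            pa, _ = path_to_root(a)
            pb, _ = path_to_root(b)
            # first common ancestor, then sum the unshared edges
            shared_anc = None
            anc_a = [n for n, _ in pa] + ["root"]
            anc_b = [n for n, _ in pb] + ["root"]
            set_b = set(anc_b)
            for n in anc_a:
                if n in set_b:
                    shared_anc = n
                    break
            d = 0.0
            for n, l in pa:
                if n == shared_anc:
                    break
                d += l
            for n, l in pb:
                if n == shared_anc:
                    break
                d += l
            result[f"{a}|{b}"] = d
    return result


def _oracle_upgma(D: np.ndarray, ids: list[str]) -> list[dict]:
    """Hand-run UPGMA merge table: repeatedly join the nearest pair of
    clusters, with average-linkage distances weighted by cluster size."""
    clusters = {i: [i] for i in range(len(ids))}
    dist = {(i, j): float(D[i, j]) for i in range(len(ids)) for j in range(i + 1, len(ids))}
    merges = []
    next_id = len(ids)
    while len(clusters) > 1:
        (a, b), dmin = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        na, nb = len(clusters[a]), len(clusters[b])
        merges.append({"join": [a, b], "height": dmin, "new": next_id})
        members = clusters.pop(a) + clusters.pop(b)
        new_dist = {}
        for (i, j), v in dist.items():
            if a in (i, j) or b in (i, j):
                continue
            new_dist[(i, j)] = v
        for c in clusters:
            key_a = (min(a, c), max(a, c))
            key_b = (min(b, c), max(b, c))
            v = (na * dist[key_a] + nb * dist[key_b]) / (na + nb)
            new_dist[(min(c, next_id), max(c, next_id))] = v
        clusters[next_id] = members
        dist = new_dist
        next_id += 1
    return merges


def make_fixtures(seed: int, outdir) -> dict:
    """Write the fixture bundle and its oracle-computed expected values.

    Contents: a 3-species / 1-site assembly fixture with hand-computed
    incidence probabilities, a 5-tip tree with brute-force cophenetic
    distances, a 6-species trait table with its UPGMA merge table, and a
    4-site toy community matrix. Returns the expected-values dict that
    is also written to ``expected_values.json``.
    """
    import math

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # 3-species assembly fixture (1-D landscape, n = d = 1)
    F = [0.5, 0.3, 0.2]
    T = [-1.0, 0.0, 1.0]
    R = [-0.5, 0.5, 1.5]
    E_site, S_site = 0.2, -0.1
    pd.DataFrame(
        {"species_id": ["a", "b", "c"], "T1": T, "R1": R, "F": F}
    ).to_csv(outdir / "assembly_pool.csv", index=False)
    pd.DataFrame(
        {"site_id": ["site1"], "S1": [S_site], "E1": [E_site]}
    ).to_csv(outdir / "assembly_site.csv", index=False)
    weights = [
        F[i]
        * math.exp(-((R[i] - S_site) ** 2) / 2.0)
        * math.exp(-((T[i] - E_site) ** 2) / 2.0)
        for i in range(3)
    ]
    total = sum(weights)
    expected_probs = [w / total for w in weights]

    # 5-tip tree: ((t1:1,t2:1)A:2,(t3:1.5,(t4:0.5,t5:0.5)C:1)B:1.5)root
    newick5 = "((t1:1,t2:1):2,(t3:1.5,(t4:0.5,t5:0.5):1):1.5);"
    (outdir / "tree5.nwk").write_text(newick5 + "\n")
    edges = {
        "t1": ("A", 1.0), "t2": ("A", 1.0), "A": ("root", 2.0),
        "t3": ("B", 1.5), "t4": ("C", 0.5), "t5": ("C", 0.5),
        "C": ("B", 1.0), "B": ("root", 1.5),
    }
    coph = _oracle_cophenetic(edges, ["t1", "t2", "t3", "t4", "t5"])

    # 6-species trait table (1-D traits keep the UPGMA table legible)
    traits = np.round(rng.normal(size=6), 2)
    ids6 = [f"s{i + 1}" for i in range(6)]
    pd.DataFrame({"species_id": ids6, "trait1": traits}).to_csv(
        outdir / "traits6.csv", index=False
    )
    D6 = np.abs(traits[:, None] - traits[None, :])
    upgma = _oracle_upgma(D6, ids6)

    # 4-site toy community over the 5 tree tips, J = 10 each
    counts = np.array(
        [[5, 5, 0, 0, 0], [0, 4, 4, 2, 0], [0, 0, 2, 4, 4], [3, 0, 0, 3, 4]]
    )
    df = pd.DataFrame(counts, columns=["t1", "t2", "t3", "t4", "t5"])
    df.insert(0, "site_id", [f"site{k + 1}" for k in range(4)])
    df.to_csv(outdir / "community4.csv", index=False)

    expected = {
        "seed": seed,
        "assembly_probabilities": expected_probs,
        "cophenetic_tree5": coph,
        "upgma_merges_traits6": upgma,
        "community4_row_sums": [10, 10, 10, 10],
    }
    (outdir / "expected_values.json").write_text(
        json.dumps(expected, indent=2, sort_keys=True)
    )
    return expected


def write_landscape_csv(landscape: Landscape, path) -> None:
    write_sites_csv(landscape, path)
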