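"""Anatomical metastasis networks, co-occurrence matrices, and
dissemination metrics.

A patient's anatomical network is the fully-connected graph over their
occupied metastatic sites. The edge count k(k-1) over k sites (ordered
pairs, so four sites give 12 edges and ten give 90) is the spatial-
heterogeneity statistic; an unordered convention (k(k-1)/2) is kept
behind a flag. Patient networks combine into a cohort network whose node
weights count patients carrying the site and whose edge weights count
patients carrying both endpoints — identical, pair for pair, to the
off-diagonal entries of the site co-occurrence matrix.

Dissemination is quantified per patient and timepoint by the number of
sites and lesions, their ratio, and two physical distances over site
centres of mass (mm): the total intersite distance (sum over unordered
site pairs of their Euclidean distance) and the maximum such distance.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import site_observations, validate_lesion_table
from .taxonomy import DEFAULT_TAXONOMY, TIMEPOINTS


def build_patient_network(sites, convention: str = "ordered") -> nx.Graph:
    """Complete graph over a patient's occupied sites.

    ``convention='ordered'`` returns a directed graph with k(k-1) edges;
    ``'unordered'`` an undirected one with k(k-1)/2. The empty site set
    yields an empty network.
    """
    sites = sorted({int(s) for s in sites})
    bad = [s for s in sites if s not in DEFAULT_TAXONOMY]
    if bad:
        raise KeyError(f"unknown site code {bad[0]}")
    if convention == "ordered":
        g: nx.Graph = nx.DiGraph()
        g.add_nodes_from(sites)
        g.add_edges_from(itertools.permutations(sites, 2))
    elif convention == "unordered":
        g = nx.Graph()
        g.add_nodes_from(sites)
        g.add_edges_from(itertools.combinations(sites, 2))
    else:
        raise ValueError("convention must be 'ordered' or 'unordered'")
    g.graph["scope"] = "patient"
    return g


def combine_networks(patient_networks) -> nx.Graph:
    """Combine patient networks into one cohort-scope weighted network.

    Node weight = number of patients carrying the site; edge weight =
    number of patients carrying both endpoints. All inputs must be
    patient-scope networks of the same edge convention.
    """
    patient_networks = list(patient_networks)
    if not patient_networks:
        g = nx.DiGraph()
        g.graph["scope"] = "cohort"
        return g
    if any(g.graph.get("scope") != "patient" for g in patient_networks):
        raise ValueError("combine_networks expects patient-scope networks")
    directed = {isinstance(g, nx.DiGraph) for g in patient_networks}
    if len(directed) != 1:
        raise ValueError("mixed edge conventions")
    out: nx.Graph = nx.DiGraph() if directed.pop() else nx.Graph()
    for g in patient_networks:
        for n in g.nodes:
            if n in out:
                out.nodes[n]["weight"] += 1
            else:
                out.add_node(n, weight=1)
        for u, v in g.edges:
            if out.has_edge(u, v):
                out[u][v]["weight"] += 1
            else:
                out.add_edge(u, v, weight=1)
    out.graph["scope"] = "cohort"
    return out


def patient_site_sets(lesion_df: pd.DataFrame, timepoint: str) -> dict[str, set[int]]:
    """Occupied site set per patient at one timepoint.

    Patients present in the table but without lesions at the timepoint
    map to the empty set (they remain in cohort summaries).
    """
    df = validate_lesion_table(lesion_df)
    patients = sorted(df["patient_id"].unique())
    at_tp = df[df["timepoint"] == timepoint]
    sets = {p: set() for p in patients}
    for pid, grp in at_tp.groupby("patient_id"):
        sets[pid] = set(grp["site_code"].astype(int))
    return sets


def edge_count_table(lesion_df: pd.DataFrame, convention: str = "ordered") -> pd.DataFrame:
    """Per-patient, per-timepoint edge counts (long format)."""
    df = validate_lesion_table(lesion_df)
    rows = []
    for tp in TIMEPOINTS:
        for pid, sites in patient_site_sets(df, tp).items():
            g = build_patient_network(sites, convention)
            rows.append((pid, tp, len(sites), g.number_of_edges()))
    return pd.DataFrame(rows, columns=["patient_id", "timepoint", "n_sites", "n_edges"])


def cooccurrence_matrix(lesion_df: pd.DataFrame, timepoint: str) -> pd.DataFrame:
    """Symmetric site x site patient-count matrix at one timepoint.

    Off-diagonal (a, b): number of patients with both sites; diagonal
    (a, a): number of patients with site a. All 15 taxonomy codes appear
    whether occupied or not.
    """
    codes = list(DEFAULT_TAXONOMY.codes)
    mat = pd.DataFrame(0, index=codes, columns=codes, dtype=int)
    for sites in patient_site_sets(lesion_df, timepoint).values():
        for a in sites:
            mat.loc[a, a] += 1
        for a, b in itertools.combinations(sorted(sites), 2):
            mat.loc[a, b] += 1
            mat.loc[b, a] += 1
    return mat


def ln_cooccurrence_fraction(lesion_df: pd.DataFrame, timepoint: str) -> float | None:
    """Percentage of lymph-node-positive patients with >= 2 distinct
    lymph-node sites; ``None`` when no patient has lymph-node disease."""
    ln_codes = set(DEFAULT_TAXONOMY.codes_in_region("lymph_node"))
    n_any = n_multi = 0
    for sites in patient_site_sets(lesion_df, timepoint).values():
        k = len(sites & ln_codes)
        if k >= 1:
            n_any += 1
        if k >= 2:
            n_multi += 1
    if n_any == 0:
        return None
    return 100.0 * n_multi / n_any


def dissemination_metrics(observations: pd.DataFrame) -> dict:
    """Dissemination metrics for one patient/timepoint's site observations.

    Distances are Euclidean, in mm, between site centres of mass over
    unordered site pairs; both distances are 0 for <= 1 site, and the
    lesion/site ratio is ``None`` for 0 sites.
    """
    if len(observations) == 0:
        return {
            "n_sites": 0,
            "n_lesions": 0,
            "lesion_site_ratio": None,
            "total_intersite_distance_mm": 0.0,
            "max_intersite_distance_mm": 0.0,
        }
    if observations["patient_id"].nunique() > 1 or observations["timepoint"].nunique() > 1:
        raise ValueError("observations must come from one patient and timepoint")
    coms = observations[["com_x_mm", "com_y_mm", "com_z_mm"]].to_numpy()
    n_sites = len(observations)
    total = 0.0
    dmax = 0.0
    for i, j in itertools.combinations(range(n_sites), 2):
        d = float(np.linalg.norm(coms[i] - coms[j]))
        total += d
        dmax = max(dmax, d)
    return {
        "n_sites": n_sites,
        "n_lesions": int(observations["n_lesions"].sum()),
        "lesion_site_ratio": float(observations["n_lesions"].sum()) / n_sites,
        "total_intersite_distance_mm": total,
        "max_intersite_distance_mm": dmax,
    }


def dissemination_table(lesion_df: pd.DataFrame) -> pd.DataFrame:
    """Dissemination metrics for every patient and timepoint.

    Patients carried in the table keep a row at every timepoint, with
    zero sites/lesions and undefined ratio where they have no disease.
    """
    df = validate_lesion_table(lesion_df)
    obs = site_observations(df)
    patients = sorted(df["patient_id"].unique())
    rows = []
    for tp in TIMEPOINTS:
        for pid in patients:
            sub = obs[(obs["patient_id"] == pid) & (obs["timepoint"] == tp)]
            m = dissemination_metrics(sub.reset_index(drop=True))
            rows.append({"patient_id": pid, "timepoint": tp, **m})
    out = pd.DataFrame(rows)
    out["lesion_site_ratio"] = out["lesion_site_ratio"].astype(float)
    return out


def presence_checker(lesion_df: pd.DataFrame) -> pd.DataFrame:
    """Long-format patient x site x timepoint presence grid.

    One row per (patient, site, timepoint) over all patients in the
    table, every taxonomy site, and all three timepoints; ``present`` is
    true iff the patient has at least one lesion of that site then.
    """
    df = validate_lesion_table(lesion_df)
    patients = sorted(df["patient_id"].unique())
    have = set(
        map(tuple, df[["patient_id", "site_code", "timepoint"]].drop_duplicates().to_numpy())
    )
    rows = [
        (pid, code, tp, (pid, code, tp) in have)
        for pid in patients
        for code in DEFAULT_TAXONOMY.codes
        for tp in TIMEPOINTS
    ]
    return pd.DataFrame(rows, columns=["patient_id", "site_code", "timepoint", "present"])
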