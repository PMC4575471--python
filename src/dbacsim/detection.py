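"""Automated bleeder detection and localization (D&L).

Pipeline: compounded power-Doppler volume -> adaptive vessel segmentation ->
3D skeletonization and centerline graph extraction -> bifurcation detection
-> spectral-Doppler gate placement on each incident branch -> resistive-index
computation -> bleeder/normal classification -> target coordinates.

The resistive index RI = (V_systole - V_diastole)/V_systole discriminates
vented (bleeder) branches, whose diastolic run-off lowers RI, from normal
branches; a branch is a bleeder iff RI < 0.75 (strict).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from . import constants as C
from .cuff import CuffGeometry
from .phantoms import (DopplerVolume, FlowWaveform, LimbPhantom, NoSignal,
                       render_power_doppler, sample_spectral_doppler)

MIN_COMPONENT_VOXELS = 20
SPUR_LENGTH_MM = 2.0
JUNCTION_MERGE_MM = 1.5
DEFAULT_GATE_DISTANCE_MM = 5.0


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def segment_vessels(vol: DopplerVolume, threshold_mode: str = "otsu",
                    threshold_value: float | None = None) -> np.ndarray:
    """Binary vessel mask from a compounded power-Doppler volume.

    ``otsu`` thresholds the nonzero intensities adaptively; ``fixed`` uses
    ``threshold_value``. Connected components smaller than 20 voxels are
    removed as noise. An empty volume yields an empty mask.
    """
    g = vol.grid
    nz = g[g > 0]
    if nz.size == 0:
        return np.zeros_like(g, dtype=bool)
    if threshold_mode == "otsu":
        if np.ptp(nz) < 1e-12:
            thr = float(nz.min()) / 2.0
        else:
            thr = float(threshold_otsu(nz))
    elif threshold_mode == "fixed":
        if threshold_value is None:
            raise ValueError("fixed threshold mode needs threshold_value")
        thr = float(threshold_value)
    else:
        raise ValueError(f"unknown threshold mode {threshold_mode!r}")
    mask = g > thr
    labels, n = ndimage.label(mask)
    if n:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        small = np.nonzero(sizes < MIN_COMPONENT_VOXELS)[0] + 1
        if small.size:
            mask &= ~np.isin(labels, small)
    return mask


# ---------------------------------------------------------------------------
# Centerline graph
# ---------------------------------------------------------------------------


@dataclass
class CenterlineGraph:
    """Polyline centerline graph in world millimeters.

    Nodes are endpoints/junctions; each edge carries its ordered polyline and
    mean lumen radius. Bifurcations are nodes of degree >= 3.
    """

    graph: nx.Graph                      # node -> attr 'point' (3,) mm
    voxel_size_mm: float

    @property
    def bifurcation_nodes(self) -> list:
        return [n for n in self.graph.nodes if self.graph.degree[n] >= 3]

    def node_point(self, n) -> np.ndarray:
        return self.graph.nodes[n]["point"]

    def edge_polyline(self, u, v) -> np.ndarray:
        poly = self.graph.edges[u, v]["polyline"]
        if np.allclose(poly[0], self.node_point(u)):
            return poly
        return poly[::-1]

    def to_json_dict(self) -> dict:
        return {
            "nodes": {str(n): self.node_point(n).tolist() for n in self.graph.nodes},
            "edges": [
                {"u": str(u), "v": str(v),
                 "polyline_mm": self.graph.edges[u, v]["polyline"].tolist(),
                 "radius_mm": self.graph.edges[u, v].get("radius_mm", 0.0)}
                for u, v in self.graph.edges
            ],
        }


def _robust_skeleton(mask: np.ndarray) -> np.ndarray:
    """3D skeleton with a coverage check.

    Lee-style thinning can erase whole limbs of a structure whose
    cross-section is an even number of voxels (a 4 x 3 bar thins to
    nothing). Where mask voxels end up far from any skeleton voxel, the
    offending region is re-skeletonized at 2x resolution and mapped back.
    """
    skel = skeletonize(mask)
    # distance (voxels) from every mask voxel to the nearest skeleton voxel
    d_skel = ndimage.distance_transform_edt(~skel)
    radius = ndimage.distance_transform_edt(mask)
    uncovered = mask & (d_skel > radius + 3.0)
    if not uncovered.any():
        return skel
    lbl, nc = ndimage.label(uncovered)
    for region in ndimage.find_objects(lbl):
        sl = tuple(slice(max(s.start - 3, 0), s.stop + 3) for s in region)
        crop = mask[sl]
        up = ndimage.zoom(crop, 2, order=0)
        sk_up = skeletonize(up)
        coords = np.unique(np.argwhere(sk_up) // 2, axis=0)
        sub = skel[sl]
        sub[tuple(coords.T)] = True
        skel[sl] = sub
    skel &= mask
    return _bridge_skeleton_gaps(skel, mask)


def _bridge_skeleton_gaps(skel: np.ndarray, mask: np.ndarray,
                          max_gap_vox: float = 6.0) -> np.ndarray:
    """Reconnect skeleton fragments separated by small in-lumen gaps
    (left behind by the re-skeletonization patch-up)."""
    struct = np.ones((3, 3, 3), bool)
    for _ in range(8):
        lbl, nc = ndimage.label(skel, structure=struct)
        if nc <= 1:
            break
        coords = [np.argwhere(lbl == k + 1) for k in range(nc)]
        bridged = False
        for a in range(nc):
            for b in range(a + 1, nc):
                d = np.linalg.norm(coords[a][:, None, :] - coords[b][None, :, :],
                                   axis=2)
                i, j = np.unravel_index(np.argmin(d), d.shape)
                if d[i, j] > max_gap_vox:
                    continue
                p, q = coords[a][i], coords[b][j]
                n_steps = int(np.ceil(d[i, j])) + 1
                line = np.round(np.linspace(p, q, n_steps)).astype(int)
                if mask[tuple(line.T)].all():
                    skel[tuple(line.T)] = True
                    bridged = True
        if not bridged:
            break
    return skel


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    """26-connectivity voxel graph of a 3D skeleton."""
    idx = np.argwhere(skel)
    index_of = {tuple(v): k for k, v in enumerate(idx)}
    G = nx.Graph()
    G.add_nodes_from(range(len(idx)))
    offsets = [np.array(o) for o in np.ndindex(3, 3, 3)
               if o != (1, 1, 1)]
    offsets = [o - 1 for o in offsets]
    for k, v in enumerate(idx):
        for o in offsets:
            nb = tuple(v + o)
            j = index_of.get(nb)
            if j is not None and j > k:
                G.add_edge(k, j, w=float(np.linalg.norm(o)))
    return G


def extract_centerlines(mask: np.ndarray, voxel_size_mm: float,
                        origin_mm: np.ndarray,
                        spur_length_mm: float = SPUR_LENGTH_MM) -> CenterlineGraph:
    """Skeletonize the vessel mask and build the polyline centerline graph.

    Spurs (leaf paths) shorter than ``spur_length_mm`` are pruned; junction
    nodes closer than 1.5 mm are merged. Edge radii come from the Euclidean
    distance transform of the mask sampled along the centerline.
    """
    if not mask.any():
        raise ValueError("empty mask: nothing to skeletonize")
    skel = _robust_skeleton(mask)
    dist = ndimage.distance_transform_edt(mask, sampling=voxel_size_mm)
    Gv = _skeleton_graph(skel)
    # 26-connectivity adds diagonal shortcuts (triangles) along any digital
    # curve; arterial trees are acyclic, so the Euclidean-weight spanning
    # tree keeps the true topology and drops the braids.
    Gv = nx.minimum_spanning_tree(Gv, weight="w")
    idx = np.argwhere(skel)

    def prune_spurs(Gv: nx.Graph) -> nx.Graph:
        # A spur is pruned when shorter than the fixed threshold or than the
        # local lumen radius at its junction (blunt tube ends skeletonize
        # into short "crow's-foot" twigs of about one radius).
        max_thresh = max(spur_length_mm, 2.0 * float(dist.max()))
        changed = True
        while changed:
            changed = False
            leaves = [n for n in Gv.nodes if Gv.degree[n] == 1]
            for leaf in leaves:
                path = [leaf]
                length = 0.0
                cur, prev = leaf, None
                while Gv.degree[cur] <= 2:
                    nbrs = [n for n in Gv.neighbors(cur) if n != prev]
                    if not nbrs:
                        break
                    nxt = nbrs[0]
                    length += Gv.edges[cur, nxt]["w"] * voxel_size_mm
                    prev, cur = cur, nxt
                    path.append(cur)
                    if length > max_thresh:
                        break
                if Gv.degree[cur] >= 3:
                    local = max(spur_length_mm,
                                2.0 * float(dist[tuple(idx[cur])]))
                    if length <= local:
                        Gv.remove_nodes_from(path[:-1])
                        changed = True
        return Gv

    Gv = prune_spurs(Gv)
    if Gv.number_of_nodes() == 0:
        raise ValueError("mask skeleton vanished after pruning")

    # Collapse degree-2 chains between key nodes into polyline edges.
    key = [n for n in Gv.nodes if Gv.degree[n] != 2]
    if not key:  # pure loop: break it at an arbitrary node
        key = [next(iter(Gv.nodes))]
    key_set = set(key)
    G = nx.Graph()
    for n in key:
        G.add_node(n, point=origin_mm + idx[n] * voxel_size_mm)
    visited_edges = set()
    for n in key:
        for nb in Gv.neighbors(n):
            if (n, nb) in visited_edges:
                continue
            poly = [n, nb]
            prev, cur = n, nb
            while cur not in key_set:
                nbrs = [m for m in Gv.neighbors(cur) if m != prev]
                if not nbrs:
                    break
                prev, cur = cur, nbrs[0]
                poly.append(cur)
            visited_edges.add((poly[-1], poly[-2]))
            visited_edges.add((n, nb))
            if poly[-1] == n and len(poly) < 3:
                continue
            pts = origin_mm + idx[poly] * voxel_size_mm
            seglen = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
            if seglen < 1e-9:
                continue
            radii = dist[tuple(idx[poly].T)]
            u, v = n, poly[-1]
            if G.has_edge(u, v) and G.edges[u, v].get("length_mm", 0) >= seglen:
                continue
            G.add_node(v, point=origin_mm + idx[v] * voxel_size_mm)
            G.add_edge(u, v, polyline=pts, radius_mm=float(np.mean(radii)),
                       length_mm=seglen)

    # Merge junction nodes lying within each other's lumen: closer than
    # 1.5 mm, or than ~the sum of the local lumen radii (duplicate skeleton
    # junctions inside one thick vessel are a single bifurcation).
    def _local_radius(n) -> float:
        radii = [G.edges[n, nb].get("radius_mm", 0.0) for nb in G.neighbors(n)]
        return max(radii) if radii else 0.0

    merged = True
    while merged:
        merged = False
        juncs = [n for n in G.nodes if G.degree[n] >= 3]
        for a in juncs:
            for b in juncs:
                if a >= b or not G.has_node(a) or not G.has_node(b):
                    continue
                pa, pb = G.nodes[a]["point"], G.nodes[b]["point"]
                thresh = max(JUNCTION_MERGE_MM,
                             1.2 * (_local_radius(a) + _local_radius(b)))
                if np.linalg.norm(pa - pb) <= thresh:
                    G = nx.contracted_nodes(G, a, b, self_loops=False)
                    merged = True
                    break
            if merged:
                break
    G.remove_edges_from(nx.selfloop_edges(G))
    return CenterlineGraph(G, voxel_size_mm)


def detect_bifurcations(graph: CenterlineGraph,
                        merge_radius_mm: float = JUNCTION_MERGE_MM) -> list[np.ndarray]:
    """Bifurcation points: graph nodes of degree >= 3, de-duplicated within
    the merge radius."""
    pts = [graph.node_point(n) for n in graph.bifurcation_nodes]
    out: list[np.ndarray] = []
    for p in pts:
        if all(np.linalg.norm(p - q) > merge_radius_mm for q in out):
            out.append(p)
    return out


# ---------------------------------------------------------------------------
# Spectral gates, RI and classification
# ---------------------------------------------------------------------------


@dataclass
class SpectralGate:
    """A spectral-Doppler sample gate on one branch incident to a bifurcation."""

    location_mm: np.ndarray
    role: str                     # proximal | distal | in-the-bleeder | unassigned
    waveform: Optional[FlowWaveform] = None
    ri: Optional[float] = None
    flagged_short_branch: bool = False


def place_sd_gates(bifurcation_node, graph: CenterlineGraph,
                   gate_distance_mm: float = DEFAULT_GATE_DISTANCE_MM,
                   tree=None) -> list[SpectralGate]:
    """Place one gate per branch incident to a bifurcation.

    Gates sit at ``gate_distance_mm`` arclength from the junction (branch
    midpoint, flagged, when the branch is shorter). Roles are assigned from
    the ground-truth flow direction when a vessel tree is supplied (proximal
    = upstream feeder); otherwise roles are left unassigned.
    """
    G = graph.graph
    if G.degree[bifurcation_node] < 3:
        raise ValueError("node is not a bifurcation (degree < 3)")
    origin = graph.node_point(bifurcation_node)
    gates: list[SpectralGate] = []
    for nb in G.neighbors(bifurcation_node):
        poly = graph.edge_polyline(bifurcation_node, nb)
        seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        total = cum[-1]
        flagged = total < gate_distance_mm
        s = total / 2.0 if flagged else gate_distance_mm
        i = int(np.searchsorted(cum, s, side="right") - 1)
        i = min(i, len(seg) - 1)
        f = (s - cum[i]) / max(seg[i], 1e-12)
        loc = poly[i] + f * (poly[i + 1] - poly[i])
        gates.append(SpectralGate(loc, "unassigned", flagged_short_branch=flagged))

    if tree is not None:
        # Upstream branch: ground-truth flow at the gate points toward the
        # junction; downstream branches point away.
        for g in gates:
            bid, dist = tree.nearest_branch(g.location_mm)
            if dist > 3.0 or bid < 0:
                continue
            br = tree.branch(bid)
            d = br.points[-1] - br.points[0]
            toward = origin - g.location_mm
            if float(d @ toward) > 0:
                g.role = "proximal"
            else:
                g.role = "in-the-bleeder" if br.flag == "bleeder" else "distal"
    return gates


def compute_ri(w: FlowWaveform) -> float:
    """Arterial resistive index (V_systole - V_diastole) / V_systole.

    Raises on non-positive systolic velocity (branch unclassifiable).
    """
    v_sys = w.v_systole
    if v_sys <= 0:
        raise ValueError("undefined RI: non-positive systolic velocity")
    return (v_sys - w.v_diastole) / v_sys


def classify_branch(ri: float,
                    threshold: float = C.RI_BLEEDER_THRESHOLD) -> str:
    """'bleeder' iff RI < threshold (strict), else 'normal'."""
    return "bleeder" if ri < threshold else "normal"


# ---------------------------------------------------------------------------
# Full D&L chain
# ---------------------------------------------------------------------------


@dataclass
class BleederCandidate:
    bifurcation_mm: np.ndarray
    branch_id: int                      # ground-truth branch id (-1 if unmatched)
    ri: float
    classification: str
    target_coordinate_mm: np.ndarray


@dataclass
class DLReport:
    """Outcome of one automated D&L run."""

    n_bifurcations: int
    bifurcations_mm: list[np.ndarray]
    bleeders: list[BleederCandidate]
    gates: list[SpectralGate]
    phase_durations_s: dict[str, float]
    errors: list[str] = field(default_factory=list)

    @property
    def total_time_s(self) -> float:
        return float(sum(self.phase_durations_s.values()))

    def to_json_dict(self) -> dict:
        return {
            "n_bifurcations": self.n_bifurcations,
            "bifurcations_mm": [p.tolist() for p in self.bifurcations_mm],
            "bleeders": [
                {"bifurcation_mm": b.bifurcation_mm.tolist(),
                 "branch_id": b.branch_id, "ri": b.ri,
                 "classification": b.classification,
                 "target_coordinate_mm": b.target_coordinate_mm.tolist()}
                for b in self.bleeders
            ],
            "phase_durations_s": self.phase_durations_s,
            "total_time_s": self.total_time_s,
            "errors": self.errors,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict()))


def run_dl(phantom: LimbPhantom, cuff: CuffGeometry, seed: int = 0,
           voxel_size_mm: float = 0.25, noise_sd: float = 2.0,
           sd_noise_sd: float = 0.05,
           gate_distance_mm: float = DEFAULT_GATE_DISTANCE_MM,
           volume: DopplerVolume | None = None) -> DLReport:
    """Run the full D&L chain and report bleeders with target coordinates.

    Phases (render, segment, centerlines, characterize) are individually
    timed; single-branch failures are recorded and the chain continues.
    """
    timings: dict[str, float] = {}
    errors: list[str] = []
    tree = phantom.vessel_tree

    t0 = time.perf_counter()
    if volume is None:
        volume = render_power_doppler(phantom, cuff, voxel_size_mm,
                                      noise_seed=seed, noise_sd=noise_sd)
    timings["acquisition"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    mask = segment_vessels(volume)
    timings["segmentation"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    bifs: list[np.ndarray] = []
    graph = None
    try:
        graph = extract_centerlines(mask, volume.voxel_size_mm, volume.origin_mm)
        bifs = detect_bifurcations(graph)
    except ValueError as exc:
        errors.append(f"centerlines: {exc}")
    timings["centerlines"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    rng = np.random.default_rng(seed)
    bleeders: list[BleederCandidate] = []
    all_gates: list[SpectralGate] = []
    if graph is not None:
        for node in graph.bifurcation_nodes:
            origin = graph.node_point(node)
            try:
                gates = place_sd_gates(node, graph, gate_distance_mm, tree=tree)
            except ValueError as exc:
                errors.append(f"gates at {origin.round(1).tolist()}: {exc}")
                continue
            all_gates.extend(gates)
            for g in gates:
                wf = sample_spectral_doppler(g.location_mm, tree,
                                             noise_seed=int(rng.integers(2**31)),
                                             noise_sd=sd_noise_sd)
                if isinstance(wf, NoSignal):
                    errors.append(f"no-signal gate at {g.location_mm.round(1).tolist()}")
                    continue
                g.waveform = wf
                try:
                    g.ri = compute_ri(wf)
                except ValueError as exc:
                    errors.append(f"RI at {g.location_mm.round(1).tolist()}: {exc}")
                    continue
                if g.role == "proximal":
                    continue  # feeder branch: not an outgoing candidate
                cls = classify_branch(g.ri)
                if cls == "bleeder":
                    bid, _ = tree.nearest_branch(g.location_mm)
                    if bid not in {c.branch_id for c in bleeders}:
                        bleeders.append(BleederCandidate(origin, bid, g.ri, cls,
                                                         g.location_mm.copy()))
    timings["characterization"] = time.perf_counter() - t0
    return DLReport(len(bifs), bifs, bleeders, all_gates, timings, errors)
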