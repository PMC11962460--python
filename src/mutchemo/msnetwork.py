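"""MS/MS molecular networking with neutral-loss annotation.

Negative-mode [M-H]- spectra are linked by the modified cosine: fragment
peaks may match either directly or shifted by the precursor mass
difference, so structural analogs that differ by one substituent (a hexose,
an N-methylanthraniloyl or a benzoyl group in the avenacin series) score
highly even though half their fragments move.  Edges whose precursor delta
matches a neutral-loss library entry are annotated with the departed group.

Default thresholds follow common molecular-networking practice: parent mass
tolerance 1 Da, fragment tolerance 0.5 Da, minimum pair cosine 0.6, minimum
matched peaks 3, minimum cluster size 2, minimum raw peak intensity 25.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

#: monoisotopic neutral-loss masses computed from elemental formulas:
#: hexosyl C6H10O5, N-methylanthraniloyl C8H7NO, benzoyl C7H4O.
DEFAULT_LOSSES: dict[str, float] = {
    "hexosyl": 162.0528,
    "N-methylanthraniloyl": 133.0528,
    "benzoyl": 104.0262,
}

NO_LOSS = "none"


@dataclass(frozen=True)
class Spectrum:
    """An MS/MS peak list with its precursor m/z.

    Peaks are kept sorted by m/z; ``processed`` marks intensity-filtered,
    sqrt-transformed, L2-normalised spectra ready for cosine scoring.
    """

    spectrum_id: str
    precursor_mz: float
    mz: np.ndarray
    intensity: np.ndarray
    polarity: str = "negative"
    processed: bool = False

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if (inten < 0).any():
            raise ValueError("intensities must be >= 0")
        if self.precursor_mz <= 0:
            raise ValueError("precursor_mz must be positive")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensity", inten[order])

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())

    @property
    def is_empty(self) -> bool:
        return self.n_peaks == 0


@dataclass(frozen=True)
class NetworkParams:
    parent_mass_tol: float = 1.0
    fragment_tol: float = 0.5
    min_cosine: float = 0.6
    min_matched_peaks: int = 3
    min_cluster_size: int = 2
    min_peak_intensity: float = 25.0
    sqrt_transform: bool = True

    def __post_init__(self) -> None:
        if self.fragment_tol <= 0 or self.parent_mass_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if not (0.0 <= self.min_cosine <= 1.0):
            raise ValueError("min_cosine must lie in [0, 1]")


def preprocess_spectrum(spectrum: Spectrum, params: NetworkParams = NetworkParams()) -> Spectrum:
    """Drop sub-threshold peaks, sqrt-transform, L2-normalise.

    Returns a new spectrum (the input is untouched); a spectrum losing all
    its peaks comes back empty and is excluded from networking downstream.
    """
    keep = spectrum.intensity >= params.min_peak_intensity
    mz = spectrum.mz[keep]
    inten = spectrum.intensity[keep].astype(float)
    if inten.size:
        if params.sqrt_transform:
            inten = np.sqrt(inten)
        inten = inten / np.linalg.norm(inten)
    else:
        logger.info("spectrum %s empty after intensity filtering", spectrum.spectrum_id)
    return replace(spectrum, mz=mz, intensity=inten, processed=True)


def modified_cosine(
    a: Spectrum, b: Spectrum, params: NetworkParams = NetworkParams()
) -> tuple[float, int]:
    """Greedy modified cosine between two preprocessed spectra.

    A peak pair (i, j) is matchable when |mz_i - mz_j| <= fragment_tol or
    |mz_i - mz_j - d| <= fragment_tol with d the precursor m/z difference.
    Pairs are accepted in descending intensity-product order, each peak used
    at most once; the score is the sum of accepted products (both spectra
    are unit vectors, so it is bounded by 1).
    """
    if not (a.processed and b.processed):
        raise ValueError("modified_cosine expects preprocessed spectra")
    if a.is_empty or b.is_empty:
        return 0.0, 0
    delta = a.precursor_mz - b.precursor_mz
    diffs = a.mz[:, None] - b.mz[None, :]
    matchable = (np.abs(diffs) <= params.fragment_tol) | (
        np.abs(diffs - delta) <= params.fragment_tol
    )
    ii, jj = np.nonzero(matchable)
    if ii.size == 0:
        return 0.0, 0
    products = a.intensity[ii] * b.intensity[jj]
    # symmetric tie-break so that score(a, b) == score(b, a)
    order = sorted(
        range(ii.size),
        key=lambda k: (
            -products[k],
            a.mz[ii[k]] + b.mz[jj[k]],
            abs(a.mz[ii[k]] - b.mz[jj[k]]),
        ),
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    score = 0.0
    matched = 0
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        score += float(products[k])
        matched += 1
    return min(score, 1.0), matched


def build_network(
    spectra: Sequence[Spectrum], params: NetworkParams = NetworkParams()
) -> nx.Graph:
    """Score all spectrum pairs and keep edges passing the GNPS-style gates.

    Nodes are non-empty preprocessed spectra (node attributes: precursor
    m/z, raw total intensity, peak count); edges require cosine >=
    ``min_cosine`` and matched peaks >= ``min_matched_peaks``; connected
    components smaller than ``min_cluster_size`` are dropped.
    """
    ids = [s.spectrum_id for s in spectra]
    if len(set(ids)) != len(ids):
        raise ValueError("spectrum ids must be unique")
    processed: dict[str, Spectrum] = {}
    graph = nx.Graph()
    for s in sorted(spectra, key=lambda s: s.spectrum_id):
        p = s if s.processed else preprocess_spectrum(s, params)
        if p.is_empty:
            continue
        processed[s.spectrum_id] = p
        graph.add_node(
            s.spectrum_id,
            precursor_mz=float(s.precursor_mz),
            total_intensity=float(s.total_intensity),
            n_peaks=int(p.n_peaks),
        )
    for id_a, id_b in itertools.combinations(sorted(processed), 2):
        pa, pb = processed[id_a], processed[id_b]
        cosine, matched = modified_cosine(pa, pb, params)
        if cosine >= params.min_cosine and matched >= params.min_matched_peaks:
            graph.add_edge(
                id_a,
                id_b,
                cosine=cosine,
                matched_peaks=matched,
                precursor_delta=float(pa.precursor_mz - pb.precursor_mz),
            )
    _drop_small_components(graph, params.min_cluster_size)
    graph.graph["params"] = params
    return graph


def _drop_small_components(graph: nx.Graph, min_cluster_size: int) -> None:
    for component in list(nx.connected_components(graph)):
        if len(component) < min_cluster_size:
            graph.remove_nodes_from(component)


def dedup_isomers(graph: nx.Graph, mass_tol: float = 0.01) -> nx.Graph:
    """Collapse same-mass (isomer) nodes within each component.

    Nodes of a component whose precursor m/z agree within ``mass_tol`` form
    an isomer group; only the member with the highest raw total intensity
    survives.  Edges are the induced subgraph among survivors, re-filtered
    for the minimum cluster size.
    """
    out = graph.copy()
    for component in list(nx.connected_components(graph)):
        nodes = sorted(component, key=lambda n: (graph.nodes[n]["precursor_mz"], n))
        group: list[str] = []
        for node in nodes + [None]:
            if group and (
                node is None
                or graph.nodes[node]["precursor_mz"] - graph.nodes[group[-1]]["precursor_mz"]
                > mass_tol
            ):
                if len(group) > 1:
                    survivor = max(
                        group, key=lambda n: (graph.nodes[n]["total_intensity"], n)
                    )
                    out.remove_nodes_from([n for n in group if n != survivor])
                group = []
            if node is not None:
                group.append(node)
    params: NetworkParams | None = graph.graph.get("params")
    if params is not None:
        _drop_small_components(out, params.min_cluster_size)
    return out


def annotate_losses(
    graph: nx.Graph,
    library: Mapping[str, float] | None = None,
    loss_tol: float = 0.1,
) -> nx.Graph:
    """Label each edge with the neutral loss its precursor delta matches.

    Adds ``loss_annotation`` (library name or ``"none"``) and
    ``nominal_loss`` (rounded |delta| in Da) to every edge, in place, and
    returns the graph.  Library entries closer together than 2 x loss_tol
    would be ambiguous and are rejected.
    """
    library = DEFAULT_LOSSES if library is None else dict(library)
    if any(m <= 0 for m in library.values()):
        raise ValueError("loss masses must be positive")
    masses = sorted(library.values())
    for m1, m2 in zip(masses, masses[1:]):
        if m2 - m1 < 2 * loss_tol:
            raise ValueError(
                f"loss library entries {m1} and {m2} overlap within 2 x loss_tol"
            )
    for _, _, attrs in graph.edges(data=True):
        delta = abs(attrs["precursor_delta"])
        attrs["nominal_loss"] = int(round(delta))
        attrs["loss_annotation"] = NO_LOSS
        for name, mass in library.items():
            if abs(delta - mass) <= loss_tol:
                attrs["loss_annotation"] = name
                break
    return graph


# ---------------------------------------------------------------------------
# MGF / GraphML / TSV I/O


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Load spectra from an MGF file (PEPMASS, CHARGE, peak lists)."""
    spectra: list[Spectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            title = str(params.get("title", f"spectrum_{i}"))
            pepmass = params["pepmass"]
            precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            charge = str(params.get("charge", ""))
            polarity = "negative" if "-" in charge else "positive"
            spectra.append(
                Spectrum(
                    spectrum_id=title,
                    precursor_mz=precursor,
                    mz=np.asarray(entry["m/z array"], dtype=float),
                    intensity=np.asarray(entry["intensity array"], dtype=float),
                    polarity=polarity,
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF with PEPMASS/CHARGE/TITLE headers."""
    entries = []
    for s in spectra:
        charge = "1-" if s.polarity == "negative" else "1+"
        entries.append(
            {
                "m/z array": s.mz,
                "intensity array": s.intensity,
                "params": {"title": s.spectrum_id, "pepmass": s.precursor_mz, "charge": charge},
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    """GraphML export with scalar attributes only."""
    export = nx.Graph()
    for node, attrs in graph.nodes(data=True):
        export.add_node(node, **{k: v for k, v in attrs.items() if np.isscalar(v)})
    for a, b, attrs in graph.edges(data=True):
        export.add_edge(a, b, **{k: v for k, v in attrs.items() if np.isscalar(v)})
    nx.write_graphml(export, str(path))


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Edge TSV: node pair, cosine, matched peaks, delta, loss annotation."""
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tcosine\tmatched_peaks\tprecursor_delta\tloss_annotation\tnominal_loss\n")
        for a, b, attrs in sorted(graph.edges(data=True)):
            fh.write(
                f"{a}\t{b}\t{attrs['cosine']:.6f}\t{attrs['matched_peaks']}\t"
                f"{attrs['precursor_delta']:.4f}\t{attrs.get('loss_annotation', '')}\t"
                f"{attrs.get('nominal_loss', '')}\n"
            )
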