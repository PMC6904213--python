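"""BioSemi-128 channel geometry: positions, scalp maps, candidate clusters.

Channel positions come from MNE's built-in ``biosemi128`` montage.  The
named 10-20 sites the analysis is organised around (Pz, Oz, C3, C4, P7,
P8) are located via the standard 10-05 montage and mapped onto the
BioSemi grid by distance, so candidate clusters and forward-model scalp
maps can be expressed in BioSemi labels without hand-curated lists.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = [
    "biosemi128_positions",
    "site_position",
    "gaussian_map",
    "candidate_cluster",
    "neighbor_weights",
    "SITES",
]

SITES = ("Pz", "Oz", "C3", "C4", "P7", "P8")


@lru_cache(maxsize=1)
def biosemi128_positions() -> dict[str, np.ndarray]:
    """Label -> 3-D position (m, head frame) for the 128 BioSemi channels."""
    import mne

    montage = mne.channels.make_standard_montage("biosemi128")
    pos = montage.get_positions()["ch_pos"]
    return {ch: np.asarray(pos[ch]) for ch in montage.ch_names}


@lru_cache(maxsize=1)
def _site_positions() -> dict[str, np.ndarray]:
    import mne

    import warnings

    for name in ("colin27_1005", "standard_1005"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", FutureWarning)
                montage = mne.channels.make_standard_montage(name)
            break
        except ValueError:
            continue
    pos = montage.get_positions()["ch_pos"]
    return {s: np.asarray(pos[s]) for s in SITES}


def site_position(site: str) -> np.ndarray:
    """Head-frame position of a named 10-20 site (m)."""
    return _site_positions()[site]


def _labels_and_coords() -> tuple[list[str], np.ndarray]:
    pos = biosemi128_positions()
    labels = sorted(pos)  # deterministic label order
    return labels, np.array([pos[c] for c in labels])


def gaussian_map(site: str, sigma: float = 0.04) -> tuple[list[str], np.ndarray]:
    """Spatial weight per channel: Gaussian in scalp distance from a site.

    ``sigma`` is in metres (default 4 cm, a broad scalp topography).
    Returns (channel labels, weights with max 1).
    """
    labels, coords = _labels_and_coords()
    d = np.linalg.norm(coords - site_position(site), axis=1)
    w = np.exp(-(d ** 2) / (2 * sigma ** 2))
    return labels, w


def candidate_cluster(site: str, n: int = 12) -> list[str]:
    """The ``n`` BioSemi channels nearest a named site (the broad cluster)."""
    labels, coords = _labels_and_coords()
    d = np.linalg.norm(coords - site_position(site), axis=1)
    order = np.lexsort((np.array(labels), d))  # distance, then label
    return [labels[i] for i in order[:n]]


def neighbor_weights(
    channel: str,
    exclude: set[str] | None = None,
    n_neighbors: int = 6,
    available: list[str] | None = None,
) -> dict[str, float]:
    """Inverse-distance weights of a channel's nearest neighbours.

    Used for artifact-channel interpolation; ``exclude`` removes other bad
    channels from the candidate pool and ``available`` restricts it to the
    channels actually present in the recording.
    """
    pos = biosemi128_positions()
    target = pos[channel]
    exclude = (exclude or set()) | {channel}
    pool = {c: pos[c] for c in (available if available is not None else pos)}
    cands = [(c, float(np.linalg.norm(p - target))) for c, p in pool.items() if c not in exclude]
    cands.sort(key=lambda cd: (cd[1], cd[0]))
    chosen = cands[:n_neighbors]
    inv = {c: 1.0 / max(d, 1e-6) for c, d in chosen}
    total = sum(inv.values())
    return {c: w / total for c, w in inv.items()}
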