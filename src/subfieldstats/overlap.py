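"""Dice spatial overlap between paired label segmentations.

DSC(A, B) = 2|A intersect B| / (|A| + |B|), computed on voxel counts of
two segmentations of the same image grid.  No resampling is performed:
the two volumes must share grid dimensions and voxel sizes, as they do
when the same scan is segmented by two algorithm versions.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .datatypes import DiceResult, LabelVolume
from .refdata import NON_TISSUE_REGIONS, V6_TO_V53_PAIRING


def _check_grids(a: LabelVolume, b: LabelVolume) -> None:
    if a.grid.shape != b.grid.shape:
        raise ValueError(
            f"grid shapes differ ({a.grid.shape} vs {b.grid.shape}); "
            "resampling is out of scope"
        )
    if not np.allclose(a.voxel_size, b.voxel_size):
        raise ValueError(
            f"voxel sizes differ ({a.voxel_size} vs {b.voxel_size})"
        )


def _dice_from_masks(mask_a: np.ndarray, mask_b: np.ndarray, name: str) -> DiceResult:
    na = int(mask_a.sum())
    nb = int(mask_b.sum())
    ni = int((mask_a & mask_b).sum())
    dsc = 2.0 * ni / (na + nb) if (na + nb) > 0 else float("nan")
    return DiceResult(label=name, dsc=dsc, voxels_a=na, voxels_b=nb,
                      voxels_intersect=ni)


def dice(a: LabelVolume, b: LabelVolume, label: int) -> DiceResult:
    """Dice coefficient of one label between two segmentations.

    If the label is absent from both volumes the DSC is undefined
    (0/0) and reported as NaN, not as 0 or 1.
    """
    _check_grids(a, b)
    name = a.label_map.get(label) or b.label_map.get(label) or str(label)
    return _dice_from_masks(a.grid == label, b.grid == label, name)


def dice_per_region(
    a: LabelVolume,
    b: LabelVolume,
    pairing: Mapping[str, Sequence[str] | str] | None = None,
    whole_exclude: Sequence[str] = NON_TISSUE_REGIONS,
) -> list[DiceResult]:
    """Per-region Dice coefficients plus a whole-structure entry.

    Parameters
    ----------
    a, b : LabelVolume
        Segmentations on the same grid; region names are resolved
        through each volume's ``label_map``.
    pairing : mapping, optional
        Region name in ``a`` -> counterpart name in ``b`` (a list takes
        its first entry, the direct counterpart).  Defaults to the
        shipped version-harmonization map restricted to regions present
        in ``a``.
    whole_exclude : sequence of str
        Region names excluded from the whole-structure union; by
        default the hippocampal fissure, a CSF cleft rather than
        tissue.  Pass ``()`` to include every foreground label.

    Returns
    -------
    list of DiceResult, one per paired region, plus one labelled
    ``"whole"`` computed on the union of (non-excluded) foreground
    labels on each side.
    """
    _check_grids(a, b)
    name_to_label_a = {v: k for k, v in a.label_map.items()}
    name_to_label_b = {v: k for k, v in b.label_map.items()}
    if pairing is None:
        pairing = {
            k: v[0] for k, v in V6_TO_V53_PAIRING.items()
            if k in name_to_label_a
        }
    results: list[DiceResult] = []
    for name_a, name_b in pairing.items():
        if not isinstance(name_b, str):
            name_b = name_b[0]
        la = name_to_label_a.get(name_a)
        lb = name_to_label_b.get(name_b)
        if la is None or lb is None:
            raise KeyError(f"region pairing {name_a!r}->{name_b!r} not found "
                           "in the volumes' label maps")
        res = _dice_from_masks(a.grid == la, b.grid == lb, name_a)
        results.append(res)

    excl_a = {name_to_label_a[n] for n in whole_exclude if n in name_to_label_a}
    excl_b = {name_to_label_b[n] for n in whole_exclude if n in name_to_label_b}
    fg_a = np.isin(a.grid, [l for l in a.labels_present() if l not in excl_a])
    fg_b = np.isin(b.grid, [l for l in b.labels_present() if l not in excl_b])
    results.append(_dice_from_masks(fg_a, fg_b, "whole"))
    return results
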