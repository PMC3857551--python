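"""Convert the stored corpus into the voxels x experiments MA matrix.

Reads results/corpus/ (written by 01_simulate_corpus.py), smooths every
peak with a 12 mm FWHM Gaussian kernel (unit peak height, voxelwise max
across peaks), and reports the matrix dimensions and sparsity. The 4D
NIfTI stack goes to scratch/ (it is bulky and reproducible).
"""

import json
from pathlib import Path

import numpy as np

from coactnet.maimage import VolumeGrid, stack_corpus
from coactnet.synthcorpus import load_corpus

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"


def main() -> None:
    grid = VolumeGrid.talairach(spacing=4.0)
    corpus = load_corpus(OUT / "corpus")
    ma = stack_corpus(corpus, grid, fwhm=12.0, combine="max")

    stats = {
        "n_voxels_in_mask": ma.n_voxels,
        "n_experiments": ma.n_experiments,
        "fraction_nonzero": float((ma.values > 1e-6).mean()),
        "max_value": float(ma.values.max()),
    }
    (OUT / "ma_summary.json").write_text(json.dumps(stats, indent=1))
    print("modeled-activation matrix:")
    for k, v in stats.items():
        print(f"  {k}: {v}")

    scratch = ROOT / "scratch"
    scratch.mkdir(exist_ok=True)
    import nibabel as nib

    nib.save(ma.to_nifti(), str(scratch / "ma_4d.nii"))
    nib.save(grid.to_nifti_mask(), str(scratch / "mask.nii"))
    print(f"  4D NIfTI written to {scratch}/ma_4d.nii")


if __name__ == "__main__":
    main()
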