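"""Regenerate the packaged 62-channel montage fixture.

Takes the 64 labels of a standard actiCAP-style 10-10 cap, drops the two
ear-adjacent sites (TP9, TP10) that realistic head models typically lack,
looks the remaining positions up in MNE's standard_1005 montage, and
projects each onto a sphere of radius 85 mm centred on the head origin.

Run from the repository root:

    python tools/make_montage_fixture.py
"""
from pathlib import Path

import mne
import numpy as np

R_HEAD_MM = 85.0

ACTICAP64 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10",
    "AF7", "AF3", "AF4", "AF8", "F5", "F1", "F2", "F6",
    "FT9", "FT7", "FC3", "FC4", "FT8", "FT10",
    "C5", "C1", "C2", "C6", "TP7", "CP3", "CPz", "CP4", "TP8",
    "P5", "P1", "P2", "P6", "PO7", "PO3", "POz", "PO4", "PO8",
]
DROPPED = {"TP9", "TP10"}


def mirror_label(ch: str) -> str:
    """10-10 left/right partner label (odd <-> even site number)."""
    head = ch.rstrip("0123456789")
    num = ch[len(head):]
    if not num:  # z-labelled midline site
        return ch
    n = int(num)
    return f"{head}{n + 1 if n % 2 else n - 1}"


def main() -> None:
    labels = [ch for ch in ACTICAP64 if ch not in DROPPED]
    assert len(labels) == 62
    montage = mne.channels.make_standard_montage("standard_1005")
    pos = montage.get_positions()["ch_pos"]
    # Symmetrize: average each site with the x-mirrored position of its
    # left/right partner so the cap is exactly mirror-symmetric, and pin
    # midline sites to x = 0.
    sym = {}
    for ch in labels:
        p = np.asarray(pos[ch], dtype=float) * 1000.0  # m -> mm
        q = np.asarray(pos[mirror_label(ch)], dtype=float) * 1000.0
        p = 0.5 * (p + q * np.array([-1.0, 1.0, 1.0]))
        if mirror_label(ch) == ch:
            p[0] = 0.0
        sym[ch] = p
    rows = []
    for ch in labels:
        p = sym[ch]
        p = p / np.linalg.norm(p) * R_HEAD_MM
        if sym[ch][0] == 0.0:
            p[0] = 0.0
        rows.append((ch, *p))
    out = Path(__file__).resolve().parents[1] / "src" / "eegxai" / "data" / "montage62.tsv"
    with out.open("w") as fh:
        fh.write("label\tx\ty\tz\n")
        for ch, x, y, z in rows:
            fh.write(f"{ch}\t{x:.4f}\t{y:.4f}\t{z:.4f}\n")
    print(f"wrote {out} ({len(rows)} channels)")


if __name__ == "__main__":
    main()
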