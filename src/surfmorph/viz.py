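"""Plot helpers: PC scatter plots with per-group convex hulls (SVG) and a
self-contained interactive 3D score scatter (HTML)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .shape_stats import ShapeSpace

__all__ = ["plot_pc_scatter", "export_scatter3d_html"]


def _group_colors(groups: list[str]) -> dict[str, tuple]:
    import matplotlib

    cmap = matplotlib.colormaps["tab10"]
    return {g: cmap(i % 10) for i, g in enumerate(groups)}


def plot_pc_scatter(
    space: ShapeSpace,
    study: pd.DataFrame,
    pcs: tuple[int, int],
    path: str | Path,
    focal: str | None = None,
) -> None:
    """Scatter of two PCs with convex hulls around each group's extreme
    points; the focal specimen (if any) is drawn as a star."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.spatial import ConvexHull, QhullError

    if space.pc_scores is None or space.variance_fraction is None:
        raise ValueError("PCA has not been fitted")
    i, j = pcs
    gmap = dict(zip(study["specimen_id"], study["group"]))
    groups = list(pd.unique(study["group"]))
    colors = _group_colors(groups)
    fig, ax = plt.subplots(figsize=(6, 5))
    for g in groups:
        rows = [
            r
            for r, sid in enumerate(space.specimen_ids)
            if gmap.get(sid) == g and sid != focal
        ]
        if not rows:
            continue
        pts = space.pc_scores[np.ix_(rows, [i, j])]
        ax.scatter(pts[:, 0], pts[:, 1], s=18, color=colors[g], label=g)
        if len(pts) >= 3:
            try:
                hull = ConvexHull(pts)
                cycle = np.append(hull.vertices, hull.vertices[0])
                ax.plot(pts[cycle, 0], pts[cycle, 1], color=colors[g], lw=0.8, alpha=0.6)
                ax.fill(pts[cycle, 0], pts[cycle, 1], color=colors[g], alpha=0.08)
            except QhullError:
                pass
    if focal is not None and focal in space.specimen_ids:
        r = space.index_of(focal)
        ax.scatter(
            space.pc_scores[r, i],
            space.pc_scores[r, j],
            marker="*",
            s=160,
            color="black",
            label=focal,
            zorder=5,
        )
    ax.set_xlabel(f"PC{i + 1} ({100 * space.variance_fraction[i]:.1f}%)")
    ax.set_ylabel(f"PC{j + 1} ({100 * space.variance_fraction[j]:.1f}%)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


_HTML_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>PC scatter 3D</title>
<style>body{margin:0;font-family:sans-serif}#c{display:block}</style></head>
<body><canvas id="c"></canvas>
<script>
const DATA = __DATA__;
const canvas = document.getElementById('c');
const ctx = canvas.getContext('2d');
let W, H; function resize(){W=canvas.width=innerWidth;H=canvas.height=innerHeight;}
resize(); addEventListener('resize', ()=>{resize(); draw();});
let rx = -1.0, rz = 0.6, dragging = false, px = 0, py = 0;
const pts = DATA.points, groups = DATA.groups, colors = DATA.colors;
let scale = 0;
for (const p of pts) scale = Math.max(scale, Math.abs(p[0]), Math.abs(p[1]), Math.abs(p[2]));
function project(p){
  const cz = Math.cos(rz), sz = Math.sin(rz), cx = Math.cos(rx), sx = Math.sin(rx);
  let x = p[0]*cz - p[1]*sz, y = p[0]*sz + p[1]*cz, z = p[2];
  let y2 = y*cx - z*sx, z2 = y*sx + z*cx;
  const s = 0.35*Math.min(W,H)/scale;
  return [W/2 + x*s, H/2 - z2*s, y2];
}
function draw(){
  ctx.clearRect(0,0,W,H);
  const order = pts.map((p,i)=>[project(p),i]).sort((a,b)=>a[0][2]-b[0][2]);
  for (const [q,i] of order){
    ctx.beginPath();
    ctx.fillStyle = colors[groups[i]];
    const r = DATA.focal === DATA.ids[i] ? 8 : 4;
    ctx.arc(q[0], q[1], r, 0, 2*Math.PI); ctx.fill();
    if (DATA.focal === DATA.ids[i]){ctx.strokeStyle='#000';ctx.stroke();}
  }
  ctx.fillStyle = '#000'; let y = 18;
  ctx.fillText('PC1 / PC2 / PC3 — drag to rotate', 10, y);
  for (const g of Object.keys(colors)){
    y += 16; ctx.fillStyle = colors[g]; ctx.fillRect(10, y-9, 10, 10);
    ctx.fillStyle = '#000'; ctx.fillText(g, 25, y);
  }
}
canvas.onmousedown = e => {dragging = true; px = e.clientX; py = e.clientY;};
onmouseup = () => dragging = false;
onmousemove = e => {
  if (!dragging) return;
  rz += (e.clientX - px) * 0.01; rx += (e.clientY - py) * 0.01;
  px = e.clientX; py = e.clientY; draw();
};
draw();
</script></body></html>
"""


def export_scatter3d_html(
    space: ShapeSpace, study: pd.DataFrame, path: str | Path, focal: str | None = None
) -> None:
    """Write a dependency-free rotatable 3D scatter of PC1-3 scores."""
    if space.pc_scores is None:
        raise ValueError("PCA has not been fitted")
    if space.pc_scores.shape[1] < 3:
        raise ValueError("need at least 3 components for the 3D scatter")
    gmap = dict(zip(study["specimen_id"], study["group"]))
    groups = [gmap.get(sid, "?") for sid in space.specimen_ids]
    uniq = list(dict.fromkeys(groups))
    cmap = _group_colors(uniq)

    def hexcolor(c):
        return "#%02x%02x%02x" % tuple(int(255 * v) for v in c[:3])

    payload = {
        "points": space.pc_scores[:, :3].tolist(),
        "ids": list(space.specimen_ids),
        "groups": groups,
        "colors": {g: hexcolor(cmap[g]) for g in uniq},
        "focal": focal,
    }
    Path(path).write_text(_HTML_TEMPLATE.replace("__DATA__", json.dumps(payload)))


def plot_r_vs_k(result, path: str | Path) -> None:
    """Correlation-vs-subsample-size curve with the baseline envelope."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ks = sorted(result.k_r)
    rs = [result.k_r[k] for k in ks]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.axhspan(result.baseline_r_min, result.baseline_r_max, color="0.85", label="baseline range")
    ax.plot(ks, rs, "o-", color="tab:blue")
    ax.set_xscale("log")
    ax.set_xlabel("subsample size k (vertices)")
    ax.set_ylabel("Pearson r vs reference iteration")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
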