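"""Emit the NEURON-ready output tree.

For a realized session this writes, under a timestamped root folder, one
self-sufficient subfolder per run containing:

* ``cell.nrn``  — hoc morphology: per-compartment section arrays with
  lengths/diameters from the SWC geometry and ``connect`` statements;
* ``nrnez.hoc`` / ``nrnez.py`` — drivers for the hoc and Python NEURON
  interfaces; both ``xopen``/load the morphology by relative path, read the
  ``.dat`` data files, instantiate the point processes (two-state kinetic
  synapses, current clamps, custom mechanisms) and schedule the events;
* per-module subfolders with ``location.dat``, ``time.dat``, ``weight.dat``
  (each headed by its "rows cols" line);
* a copy of the source ``.swc`` and any custom ``.mod`` payloads.

Weights are converted from user-facing nS to NEURON's uS here and nowhere
else.  All paths inside the tree are relative, so folders are relocatable.
"""

from __future__ import annotations

import re
import shutil
import subprocess
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np

from .morphology import (
    Compartment,
    Morphology,
    SectionGeometry,
    section_geometry,
    write_swc,
)
from .placement import PlacedEnsemble, realize
from .stimspec import Session, point_process_name, validate_session

__all__ = [
    "DatError",
    "OutputTree",
    "write_dat",
    "read_dat",
    "write_nrn",
    "write_drivers",
    "generate",
    "NS_TO_US",
    "EPSILON_LENGTH_UM",
]

NS_TO_US = 1e-3  # 1 nS = 0.001 uS
EPSILON_LENGTH_UM = 0.01  # substituted for zero-length sections, with a warning


class DatError(ValueError):
    """A .dat table is ragged or its header disagrees with its body."""


@dataclass
class OutputTree:
    root: Path
    run_dirs: list[Path] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _fmt(v: float) -> str:
    return format(float(v), ".10g")


def write_dat(table) -> str:
    """Serialize a rectangular numeric matrix: "R C" header, then R rows."""
    rows = [list(r) for r in table]
    ncols = {len(r) for r in rows}
    if len(ncols) > 1:
        raise DatError(f"ragged table: row lengths {sorted(ncols)}")
    n_rows = len(rows)
    n_cols = ncols.pop() if ncols else 0
    if n_rows and n_cols == 0:
        n_rows = 0  # rows of width zero carry no data
    lines = [f"{n_rows} {n_cols}"]
    lines += [" ".join(_fmt(v) for v in r) for r in rows[:n_rows]]
    return "\n".join(lines) + "\n"


def read_dat(text: str) -> np.ndarray:
    """Parse .dat text back into a (rows, cols) array, checking the header."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise DatError("empty .dat text")
    try:
        n_rows, n_cols = (int(v) for v in lines[0].split())
    except ValueError:
        raise DatError(f"bad header line {lines[0]!r}") from None
    body = [[float(v) for v in ln.split()] for ln in lines[1:]]
    arr = np.array(body, dtype=float).reshape(len(body), -1 if body else 0)
    if arr.shape != (n_rows, n_cols) and not (n_rows == 0 and arr.size == 0):
        raise DatError(f"header {n_rows}x{n_cols} != body {arr.shape}")
    return arr.reshape(n_rows, n_cols)


# ---------------------------------------------------------------------------
# Morphology -> hoc (.nrn)

_HOC_ARRAYS = {
    Compartment.soma: "soma",
    Compartment.axon: "axon",
    Compartment.basal: "basal",
    Compartment.apical: "apical",
}


def _geometries(
    m: Morphology, use_3d: bool, warnings: list[str] | None = None
) -> dict[int, SectionGeometry]:
    geoms: dict[int, SectionGeometry] = {}
    for p in m.points:
        if p.compartment is None:
            continue
        g = section_geometry(p, m.parent_of(p), use_3d=use_3d)
        if g.length == 0:
            if warnings is not None:
                warnings.append(
                    f"point {p.id}: zero-length section, using "
                    f"{EPSILON_LENGTH_UM} um"
                )
            g = SectionGeometry(length=EPSILON_LENGTH_UM, diameter=g.diameter)
        geoms[p.id] = g
    return geoms


def write_nrn(
    m: Morphology, use_3d: bool = False, warnings: list[str] | None = None
) -> str:
    """hoc text declaring the cell: create, geometry, connect statements."""
    geoms = _geometries(m, use_3d, warnings)
    lines = ["// cell morphology generated from SWC"]
    counts = m.counts
    for comp, name in _HOC_ARRAYS.items():
        n = counts[comp.value]
        if n:
            lines.append(f"create {name}[{n}]")
    for comp, name in _HOC_ARRAYS.items():
        for i, pid in enumerate(m.sections[comp]):
            g = geoms[pid]
            lines.append(
                f"{name}[{i}] {{ L = {_fmt(g.length)}  diam = {_fmt(g.diameter)} }}"
            )
    n_connect = 0
    for p in m.points:
        if p.compartment is None or p.parent_id == -1:
            continue
        parent = m.parent_of(p)
        if parent.compartment is None:
            if warnings is not None:
                warnings.append(
                    f"point {p.id}: parent {parent.id} has no canonical "
                    "compartment; connect skipped"
                )
            continue
        child_ref = m.ref_of_id(p.id)
        parent_ref = m.ref_of_id(parent.id)
        lines.append(
            f"connect {_HOC_ARRAYS[child_ref.compartment]}[{child_ref.index}](0), "
            f"{_HOC_ARRAYS[parent_ref.compartment]}[{parent_ref.index}](1)"
        )
        n_connect += 1
    lines.append(f"// {n_connect} connections")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Drivers

_IDENT_RE = re.compile(r"[^0-9A-Za-z_]")


def _ident(name: str) -> str:
    s = _IDENT_RE.sub("_", name)
    return ("m_" + s) if (not s or s[0].isdigit()) else s


def _module_rows(s: Session, e: PlacedEnsemble, module_name: str):
    """(location, time, weight) rows for one module across all of its tags."""
    tags_with = {t.name for t in s.tags if module_name in t.module_names}
    loc, tim, wgt = [], [], []
    mod = s.module(module_name)
    unit = 1.0 if mod.kind == "istep" else NS_TO_US  # nA stays, nS -> uS
    for inp in e.inputs:
        if inp.tag_name not in tags_with:
            continue
        ref = inp.segment
        loc.append([ref.compartment.code, ref.index, ref.position])
        tim.append([inp.time])
        wgt.append([inp.weights[module_name] * unit])
    return loc, tim, wgt


_HOC_PICK = """\
// return a point process of the right class at (code, index, position)
obfunc {fn}() {{ localobj pp
  if ($1 == 1) {{ soma[$2] pp = new {cls}($3) }}
  if ($1 == 2) {{ axon[$2] pp = new {cls}($3) }}
  if ($1 == 3) {{ basal[$2] pp = new {cls}($3) }}
  if ($1 == 4) {{ apical[$2] pp = new {cls}($3) }}
  return pp
}}
"""


def write_drivers(s: Session, e: PlacedEnsemble, nrn_name: str = "cell.nrn"):
    """(hoc_text, py_text) for the nrnez.hoc / nrnez.py drivers."""
    hoc = [
        "// NEURON driver (hoc interface)",
        f'xopen("{nrn_name}")',
        "objref datfile",
        "datfile = new File()",
        "",
    ]
    py = [
        '"""NEURON driver (Python interface)."""',
        "from neuron import h",
        "",
        f'h.xopen("{nrn_name}")',
        "",
        "SECTIONS = {1: h.soma, 2: h.axon, 3: h.basal, 4: h.apical}",
        "",
        "def read_dat(path):",
        "    with open(path) as f:",
        "        lines = [ln.split() for ln in f if ln.strip()]",
        "    n_rows, n_cols = int(lines[0][0]), int(lines[0][1])",
        "    rows = [[float(v) for v in ln] for ln in lines[1:1 + n_rows]]",
        "    assert all(len(r) == n_cols for r in rows)",
        "    return rows",
        "",
        "_keep = []  # prevent garbage collection of point processes",
        "",
    ]
    for mod in s.modules:
        name = _ident(mod.name)
        if mod.kind == "synaptic":
            cls = "Exp2Syn"
        elif mod.kind == "istep":
            cls = "IClamp"
        else:
            cls = point_process_name(mod.mod_source or "") or name
        # --- hoc ---
        hoc.append(f"// module {mod.name} ({mod.kind})")
        hoc.append(_HOC_PICK.format(fn=f"{name}_make", cls=cls))
        hoc += [
            f'datfile.ropen("{mod.name}/location.dat")',
            f"{name}_n = datfile.scanvar()",
            "datfile.scanvar() // n columns",
            f"objref {name}_pp[{name}_n]",
            f"for i = 0, {name}_n - 1 {{",
            "  code = datfile.scanvar()",
            "  idx = datfile.scanvar()",
            "  pos = datfile.scanvar()",
            f"  {name}_pp[i] = {name}_make(code, idx, pos)",
            "}",
            "datfile.close()",
            f'datfile.ropen("{mod.name}/time.dat")',
            "datfile.scanvar() datfile.scanvar()",
            f"double {name}_t[{name}_n]",
            f"for i = 0, {name}_n - 1 {{ {name}_t[i] = datfile.scanvar() }}",
            "datfile.close()",
            f'datfile.ropen("{mod.name}/weight.dat")',
            "datfile.scanvar() datfile.scanvar()",
            f"double {name}_w[{name}_n]",
            f"for i = 0, {name}_n - 1 {{ {name}_w[i] = datfile.scanvar() }}",
            "datfile.close()",
        ]
        if mod.kind == "synaptic":
            hoc += [
                f"objref {name}_ns[{name}_n], {name}_nc[{name}_n]",
                f"for i = 0, {name}_n - 1 {{",
                f"  {name}_pp[i].tau1 = {_fmt(mod.tau1)}",
                f"  {name}_pp[i].tau2 = {_fmt(mod.tau2)}",
                f"  {name}_pp[i].e = {_fmt(mod.E)}",
                f"  {name}_ns[i] = new NetStim()",
                f"  {name}_ns[i].number = 1",
                f"  {name}_ns[i].start = {name}_t[i]",
                f"  {name}_nc[i] = new NetCon({name}_ns[i], {name}_pp[i])",
                f"  {name}_nc[i].weight = {name}_w[i]",
                f"  {name}_nc[i].delay = 0",
                "}",
            ]
        elif mod.kind == "istep":
            hoc += [
                f"for i = 0, {name}_n - 1 {{",
                f"  {name}_pp[i].del = {name}_t[i]",
                f"  {name}_pp[i].dur = {_fmt(mod.duration)}",
                f"  {name}_pp[i].amp = {name}_w[i]",
                "}",
            ]
        else:
            hoc += [
                f"objref {name}_ns[{name}_n], {name}_nc[{name}_n]",
                f"for i = 0, {name}_n - 1 {{",
                f"  {name}_ns[i] = new NetStim()",
                f"  {name}_ns[i].number = 1",
                f"  {name}_ns[i].start = {name}_t[i]",
                f"  {name}_nc[i] = new NetCon({name}_ns[i], {name}_pp[i])",
                f"  {name}_nc[i].weight = {name}_w[i]",
                f"  {name}_nc[i].delay = 0",
                "}",
            ]
        hoc.append("")
        # --- python ---
        py.append(f"# module {mod.name} ({mod.kind})")
        py += [
            f'{name}_loc = read_dat("{mod.name}/location.dat")',
            f'{name}_t = [r[0] for r in read_dat("{mod.name}/time.dat")]',
            f'{name}_w = [r[0] for r in read_dat("{mod.name}/weight.dat")]',
            f"for (code, idx, pos), t, w in zip({name}_loc, {name}_t, {name}_w):",
            f"    sec = SECTIONS[int(code)][int(idx)]",
            f"    pp = h.{cls}(sec(pos))",
        ]
        if mod.kind == "synaptic":
            py += [
                f"    pp.tau1 = {_fmt(mod.tau1)}",
                f"    pp.tau2 = {_fmt(mod.tau2)}",
                f"    pp.e = {_fmt(mod.E)}",
                "    ns = h.NetStim()",
                "    ns.number = 1",
                "    ns.start = t",
                "    nc = h.NetCon(ns, pp)",
                "    nc.weight[0] = w",
                "    nc.delay = 0",
                "    _keep.append((pp, ns, nc))",
            ]
        elif mod.kind == "istep":
            py += [
                "    pp.delay = t",
                f"    pp.dur = {_fmt(mod.duration)}",
                "    pp.amp = w",
                "    _keep.append(pp)",
            ]
        else:
            py += [
                "    ns = h.NetStim()",
                "    ns.number = 1",
                "    ns.start = t",
                "    nc = h.NetCon(ns, pp)",
                "    nc.weight[0] = w",
                "    nc.delay = 0",
                "    _keep.append((pp, ns, nc))",
            ]
        py.append("")
    return "\n".join(hoc) + "\n", "\n".join(py) + "\n"


# ---------------------------------------------------------------------------
# Full tree generation


def _unique_dir(base: Path) -> Path:
    if not base.exists():
        return base
    i = 1
    while (cand := base.with_name(f"{base.name}-{i}")).exists():
        i += 1
    return cand


def generate(
    s: Session,
    m: Morphology,
    out_dir: str | Path | None = None,
    timestamp: str | None = None,
    use_3d: bool = False,
    compile_mods: bool = False,
    poisson_mode: str = "scaled",
) -> OutputTree:
    """Realize every run of the session and write the complete output tree.

    The root folder is named by timestamp (YYYYMMDD-HHMMSS; pass
    ``timestamp`` to pin it for reproducible trees); name collisions get a
    ``-1``, ``-2`` ... suffix.  ``compile_mods=True`` additionally invokes
    ``nrnivmodl`` in each run folder (requires NEURON on PATH; off by
    default since the emitted files, not the compilation, are the product).
    """
    errors = validate_session(s, m)
    if errors:
        raise ValueError("session is not generatable: " + "; ".join(errors))
    stamp = timestamp or datetime.now().strftime("%Y%m%d-%H%M%S")
    out_base = Path(out_dir) if out_dir is not None else Path(s.output_path)
    root = _unique_dir(out_base / stamp)
    tree = OutputTree(root=root)
    root.mkdir(parents=True)

    swc_src = Path(s.swc_path)
    swc_name = swc_src.name if swc_src.name.endswith(".swc") else "cell.swc"
    nrn_text = write_nrn(m, use_3d=use_3d, warnings=tree.warnings)
    swc_text = swc_src.read_text() if swc_src.is_file() else write_swc(m)

    for run in range(s.n_runs):
        run_dir = root / f"run-{run}"
        run_dir.mkdir()
        tree.run_dirs.append(run_dir)
        ensemble = realize(s, m, run_index=run, poisson_mode=poisson_mode)
        hoc_text, py_text = write_drivers(s, ensemble)
        (run_dir / "cell.nrn").write_text(nrn_text)
        (run_dir / "nrnez.hoc").write_text(hoc_text)
        (run_dir / "nrnez.py").write_text(py_text)
        (run_dir / swc_name).write_text(swc_text)
        for mod in s.modules:
            mod_dir = run_dir / mod.name
            mod_dir.mkdir()
            loc, tim, wgt = _module_rows(s, ensemble, mod.name)
            (mod_dir / "location.dat").write_text(write_dat(loc))
            (mod_dir / "time.dat").write_text(write_dat(tim))
            (mod_dir / "weight.dat").write_text(write_dat(wgt))
            if mod.kind == "custom" and mod.mod_source:
                (run_dir / f"{mod.name}.mod").write_text(mod.mod_source)
        if compile_mods:
            if shutil.which("nrnivmodl") is None:
                raise RuntimeError("nrnivmodl not found on PATH")
            subprocess.run(["nrnivmodl"], cwd=run_dir, check=True)
    return tree
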