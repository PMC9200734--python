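# Measurement-record schema

One JSON object per subject. All blocks are optional — supply whichever
inputs the methods you want to run require. Lengths are in cm, areas in
cm² unless the top-level `"units"` key says `"mm"`, in which case lengths
are divided by 10 and areas by 100 on read.

| Block | Required by | Fields |
|---|---|---|
| `linear` | `dev`, `teichholz` | `ivs_cm`, `lvid_cm`, `pwt_cm` |
| `sax` | `novel`, `al`, `te` | `a1_cm2` (epicardial), `a2_cm2` (endocardial), `level` (`mitral` / `chordae` / `mid_papillary`, default `chordae`) |
| `long_axis` | `al`, `te` | `a_cm` (apex → SAX plane), `d_cm` (SAX plane → mitral plane) |
| `disc_stack` | `novel`, `bp`, `biplane-edv` | `semi_axes` (list of `[a_4ch, b_2ch]` pairs, base → apex), `length_4ch_cm`, `length_2ch_cm` |
| `disc_stack_epi` | `bp` | same layout as `disc_stack` |
| `contour_4ch`, `contour_2ch` | alternative to `disc_stack` | `points` (ordered `[x, y]` vertices), `base_left`, `base_right`, `apex` |
| `subject` | indexing / classification | `id`, `age_years`, `sex` (`M`/`F`), `bsa_m2` |

If `disc_stack` is absent but both contours are present, the stack is
derived by slicing the contours into `--n-discs` equal-height discs
(chord widths sampled at disc mid-levels perpendicular to the base-midpoint
→ apex axis).

## Mapping from vendor exports

Workstation software exports per-disc diameters of the biplane delineation
(one list per apical view, base → apex) plus the long-axis length of each
view. Halve the diameters to obtain the `semi_axes` pairs, and copy the
view lengths into `length_4ch_cm` / `length_2ch_cm`. Traced SAX areas paste
directly into `sax`; if the export is in mm/mm², set `"units": "mm"`.

See `example_record.json` for a complete file (a cylindrical cavity of
radius 2 cm and length 8 cm with a 1 cm wall).
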