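# fins

Automated counting of nuclei and marker-positive nuclei in multi-channel
immunofluorescence images.

Quantifying proliferation (Ki67) or DNA damage (γH2AX) in cultured cells
usually means a researcher counting, by eye, every DAPI-stained nucleus in a
field and then every nucleus containing marker signal. `fins` automates that
workflow: it segments the nuclear regions from the DAPI counterstain, then
scores each nucleus for the presence of co-localised signal in each marker
channel, and writes per-image counts to a CSV with reviewable overlay
images. It is aimed at cell biologists batch-processing folders of exported
TIFF acquisitions, and at anyone who wants a tested, scriptable
implementation of this counting procedure.

## Method

Nuclear regions are computed by two-phase convex variational segmentation of
the normalised DAPI channel z<sub>δ</sub>(x) ∈ [0,1]:

```
min_{u ∈ [0,1]}  ∫_Ω |∇u(x)| dx  +  λ ∫_Ω f(x) u(x) dx,      f(x) = t_δ − z_δ(x)
```

where t<sub>δ</sub> is an Otsu threshold of the channel histogram and λ = 20
by default. The total-variation term penalises interface length, so isolated
noise pixels that survive plain thresholding are removed while genuine
nuclear boundaries are kept. Because the relaxed problem is convex, the
minimiser u\* (computed with a Split Bregman scheme) is approximately binary
and any level β ∈ (0,1) of it yields a global minimiser of the binary
problem; the nuclear foreground is Ω_D = {u\* > β} with β = 0.5. Connected
components Ω_D¹ … Ω_Dⁿ of Ω_D are the n nuclei.

Each marker channel z<sub>χ</sub> gets one global Otsu threshold
t<sub>χ</sub> with a floor t<sub>f</sub> = 0.1 (applied when Otsu lands
below it, e.g. on channels with little or no signal). Nucleus i is positive
for the marker iff z<sub>χ</sub>(x) > t<sub>χ</sub> for some pixel
x ∈ Ω_D<sup>i</sup> — presence/absence only, so each marker count is at most n.

The package also implements the concordance metrics used to compare
automated counts against several human raters (distance to the rater
centroid in (DAPI, marker) count space, percentage concordance, signed
percent outside the rater range), and a synthetic-image generator that
renders fields of elliptical nuclei with known ground truth for testing.

## Worked example

```python
from fins import ChannelMapping, FixtureSpec, generate_fixture, process_image

channels, truth = generate_fixture(FixtureSpec(seed=1))   # 512x512, 3 channels
mapping = ChannelMapping(counterstain_channel=0,
                         marker_channels=((1, "Ki67"), (2, "gH2AX")))
record = process_image(channels, mapping, image_name="demo")
print(f"{record.image_name}: DAPI={record.n_nuclei}", dict(record.marker_counts))
print("ground truth:", truth.n_nuclei, {k: len(v) for k, v in truth.positive_ids.items()})
```

prints

```
demo: DAPI=30 {'Ki67': 12, 'gH2AX': 18}
ground truth: 30 {'Ki67': 12, 'gH2AX': 18}
```

i.e. on a noisy synthetic field (Gaussian noise, hot-pixel speckles, dim
detritus, border-cropped nuclei) the pipeline recovers all 30 nuclei, the 12
Ki67-positive and the 18 γH2AX-positive nuclei exactly.

From a shell, point the batch driver at a folder of multi-plane TIFFs:

```
fins count ./images --out ./results --dapi-channel 2 \
    --marker Ki67:0 --marker gH2AX:1 --overlay
```

which writes `fins_counts_<timestamp>.csv` (one row per image: name, DAPI
count, one column per marker) plus a `*_overlay.png` per image showing the
segmented regions with contours on marker-positive nuclei.

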