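# chromaharmony

Multi-color feature extraction and color-harmony scoring for raster images.

Given an RGB image, the pipeline smooths away edge/semantic structure with a
circular mean filter, converts to CIELAB, builds a dominant-color palette by
K-means, segments the grayscale by watershed immersion, and summarizes the
result as a 16-dimensional physical feature vector (color moments, grayscale
entropy, space density, color-tone / lightness / cool-warm contrast, palette
area difference). A bundled linear model maps min-max-normalized features to
a harmony score on a 5-level scale; utilities cover model fitting (OLS with
optional backward elimination), k-fold cross-validated evaluation
(Pearson r / MAE / RMSE / accuracy), Cronbach's alpha for rating matrices,
and a pleasure/arousal → harmony linear map.

## Library overview

```python
import numpy as np
from chromaharmony import features, harmony_model, synthetic

img = synthetic.make_noise(64, 64, seed=0)          # any (H, W, 3) RGB in [0, 1]
vec = features.extract_all(img, smooth_radius=10)   # FeatureVector f1..f16

model = harmony_model.reference_model()             # bundled linear model
score = model.predict({name: 0.0 for name in model.feature_names})  # 0.249
```

Modules: `colorspace` (RGB↔CIELAB, hue/chroma), `preprocess` (circular mean
filter, BT.709 grayscale), `palette` (K-means palette + proportional strip),
`segmentation` (watershed by immersion), `features` (f1..f16),
`harmony_model` (normalization, prediction, fitting, metrics, reliability),
`synthetic` (fixture generators with ground truth), `cli`.

## CLI

Installed as `chromaharmony`. Subcommands:

```sh
chromaharmony synth --kind blocks --colors '1,0,0;0,0,1' --proportions 0.7,0.3 --out blocks.png
chromaharmony smooth input.png smoothed.png --smooth-radius 50
chromaharmony palette input.png --out-strip strip.png --out-csv palette.csv --j 8
chromaharmony segment input.png --out-png labels.png --out-csv sizes.csv
chromaharmony extract images/ --out features.csv
chromaharmony score --features features.csv --batch-norm --out scores.csv
chromaharmony train --features rated.csv --target-col harmony --out model.json
chromaharmony evaluate --features rated.csv --task regression --k 10
chromaharmony reliability --ratings ratings.csv
```

Note on `score`: the bundled model expects min-max-normalized inputs and its
original normalization bounds are not published, so scoring raw features
requires either `--norm bounds.json` or `--batch-norm` (fit min/max on the
scored batch). Defaults: smoothing radius 50 px, 8 palette colors,
8-connectivity, 10 CV folds, classification threshold 0 (a score strictly
greater than the threshold is "harmonious").

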