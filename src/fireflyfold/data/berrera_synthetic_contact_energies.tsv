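# SYNTHETIC contact-energy matrix (hydropathy-product surrogate).
# This is NOT the published Berrera et al. matrix: it is a constructed
# stand-in, e(u,v) = -0.025*(KD(u)+4.5)*(KD(v)+4.5) - 0.2 with KD the
# Kyte-Doolittle hydropathy, provided so the FCC contact-matrix pipeline
# runs end-to-end. Energies computed with it are not comparable to
# published reference values.
# sha256(body) = 62f7ddde9ebcb5b6f7397d2fd4c7f12ff2c217d9c558606186d67d046090420e
a	c	d	e	f	g	h	i	k	l	m	n	p	q	r	s	t	v	w	y
a	-1.192
c	-1.302	-1.425
d	-0.358	-0.375	-0.225
e	-0.358	-0.375	-0.225	-0.225
f	-1.350	-1.477	-0.383	-0.383	-1.532
g	-0.846	-0.917	-0.302	-0.302	-0.948	-0.620
h	-0.405	-0.427	-0.233	-0.233	-0.437	-0.333	-0.242
i	-1.617	-1.775	-0.425	-0.425	-1.843	-1.123	-0.492	-2.225
k	-0.295	-0.305	-0.215	-0.215	-0.309	-0.262	-0.220	-0.335	-0.209
l	-1.507	-1.653	-0.408	-0.408	-1.715	-1.051	-0.470	-2.068	-0.325	-1.922
m	-1.208	-1.320	-0.360	-0.360	-1.368	-0.856	-0.408	-1.640	-0.296	-1.528	-1.224
n	-0.358	-0.375	-0.225	-0.225	-0.383	-0.302	-0.233	-0.425	-0.215	-0.408	-0.360	-0.225
p	-0.657	-0.708	-0.273	-0.273	-0.729	-0.497	-0.294	-0.853	-0.244	-0.802	-0.664	-0.273	-0.410
q	-0.358	-0.375	-0.225	-0.225	-0.383	-0.302	-0.233	-0.425	-0.215	-0.408	-0.360	-0.225	-0.273	-0.225
r	-0.200	-0.200	-0.200	-0.200	-0.200	-0.200	-0.200	-0.200	-0.200	-0.200	-0.200	-0.200	-0.200	-0.200	-0.200
s	-0.783	-0.848	-0.293	-0.293	-0.875	-0.579	-0.320	-1.033	-0.256	-0.968	-0.792	-0.293	-0.468	-0.293	-0.200	-0.542
t	-0.798	-0.865	-0.295	-0.295	-0.893	-0.589	-0.324	-1.055	-0.257	-0.989	-0.808	-0.295	-0.475	-0.295	-0.200	-0.552	-0.561
v	-1.570	-1.722	-0.417	-0.417	-1.788	-1.092	-0.483	-2.158	-0.331	-2.005	-1.592	-0.417	-0.831	-0.417	-0.200	-1.005	-1.026	-2.092
w	-0.767	-0.830	-0.290	-0.290	-0.857	-0.569	-0.317	-1.010	-0.254	-0.947	-0.776	-0.290	-0.461	-0.290	-0.200	-0.533	-0.542	-0.983	-0.524
y	-0.704	-0.760	-0.280	-0.280	-0.784	-0.528	-0.304	-0.920	-0.248	-0.864	-0.712	-0.280	-0.432	-0.280	-0.200	-0.496	-0.504	-0.896	-0.488	-0.456
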