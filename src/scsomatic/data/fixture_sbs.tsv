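category	TS1	TS2	TS3	TS4	TS5
A[C>A]A	0.063981	0.012416	0.001042	0.001042	0.001042
A[C>A]C	0.020538	0.009373	0.001042	0.001042	0.001042
A[C>A]G	0.084944	0.010071	0.001042	0.001042	0.001042
A[C>A]T	0.032572	0.011357	0.001042	0.001042	0.001042
C[C>A]A	0.052781	0.012747	0.001042	0.001042	0.001042
C[C>A]C	0.029135	0.008823	0.001042	0.001042	0.001042
C[C>A]G	0.076049	0.008886	0.001042	0.001042	0.001042
C[C>A]T	0.068715	0.009573	0.001042	0.001042	0.001042
G[C>A]A	0.054692	0.008594	0.001042	0.001042	0.001042
G[C>A]C	0.004015	0.01225	0.001042	0.001042	0.001042
G[C>A]G	0.070766	0.009273	0.001042	0.001042	0.001042
G[C>A]T	0.048521	0.012037	0.001042	0.001042	0.001042
T[C>A]A	0.070617	0.009247	0.001042	0.001042	0.001042
T[C>A]C	0.036392	0.009454	0.001042	0.001042	0.001042
T[C>A]G	0.060072	0.009639	0.001042	0.001042	0.001042
T[C>A]T	0.159542	0.007358	0.001042	0.001042	0.001042
A[C>G]A	0.000833	0.010233	0.001042	0.001042	0.010385
A[C>G]C	0.000833	0.009759	0.001042	0.001042	0.045785
A[C>G]G	0.000833	0.011155	0.001042	0.001042	0.041524
A[C>G]T	0.000833	0.010525	0.001042	0.001042	0.007575
C[C>G]A	0.000833	0.011207	0.001042	0.001042	0.048859
C[C>G]C	0.000833	0.012644	0.001042	0.001042	0.082371
C[C>G]G	0.000833	0.012073	0.001042	0.001042	0.108433
C[C>G]T	0.000833	0.010488	0.001042	0.001042	0.021917
G[C>G]A	0.000833	0.009295	0.001042	0.001042	0.018784
G[C>G]C	0.000833	0.009315	0.001042	0.001042	0.074063
G[C>G]G	0.000833	0.014288	0.001042	0.001042	0.040206
G[C>G]T	0.000833	0.011394	0.001042	0.001042	0.057725
T[C>G]A	0.000833	0.011525	0.001042	0.001042	0.15175
T[C>G]C	0.000833	0.009794	0.001042	0.001042	0.065192
T[C>G]G	0.000833	0.008863	0.001042	0.001042	0.108047
T[C>G]T	0.000833	0.011302	0.001042	0.001042	0.03405
A[C>T]A	0.000833	0.010615	0.001042	0.001042	0.001042
A[C>T]C	0.000833	0.009776	0.001042	0.001042	0.001042
A[C>T]G	0.000833	0.010124	0.221406	0.001042	0.001042
A[C>T]T	0.000833	0.007572	0.001042	0.001042	0.001042
C[C>T]A	0.000833	0.009983	0.001042	0.001042	0.001042
C[C>T]C	0.000833	0.011005	0.001042	0.001042	0.001042
C[C>T]G	0.000833	0.013872	0.185894	0.001042	0.001042
C[C>T]T	0.000833	0.013278	0.001042	0.001042	0.001042
G[C>T]A	0.000833	0.007366	0.001042	0.001042	0.001042
G[C>T]C	0.000833	0.007402	0.001042	0.001042	0.001042
G[C>T]G	0.000833	0.009016	0.296443	0.001042	0.001042
G[C>T]T	0.000833	0.012527	0.001042	0.001042	0.001042
T[C>T]A	0.000833	0.009139	0.001042	0.001042	0.001042
T[C>T]C	0.000833	0.009765	0.001042	0.001042	0.001042
T[C>T]G	0.000833	0.008079	0.200423	0.001042	0.001042
T[C>T]T	0.000833	0.012403	0.001042	0.001042	0.001042
A[T>A]A	0.000833	0.01216	0.001042	0.001042	0.001042
A[T>A]C	0.000833	0.008477	0.001042	0.001042	0.001042
A[T>A]G	0.000833	0.009602	0.001042	0.001042	0.001042
A[T>A]T	0.000833	0.010107	0.001042	0.001042	0.001042
C[T>A]A	0.000833	0.013129	0.001042	0.001042	0.001042
C[T>A]C	0.000833	0.012192	0.001042	0.001042	0.001042
C[T>A]G	0.000833	0.008497	0.001042	0.001042	0.001042
C[T>A]T	0.000833	0.013758	0.001042	0.001042	0.001042
G[T>A]A	0.000833	0.010093	0.001042	0.001042	0.001042
G[T>A]C	0.000833	0.012859	0.001042	0.001042	0.001042
G[T>A]G	0.000833	0.008513	0.001042	0.001042	0.001042
G[T>A]T	0.000833	0.010808	0.001042	0.001042	0.001042
T[T>A]A	0.000833	0.008175	0.001042	0.001042	0.001042
T[T>A]C	0.000833	0.011771	0.001042	0.001042	0.001042
T[T>A]G	0.000833	0.011815	0.001042	0.001042	0.001042
T[T>A]T	0.000833	0.006231	0.001042	0.001042	0.001042
A[T>C]A	0.000833	0.013697	0.001042	0.084288	0.001042
A[T>C]C	0.000833	0.010219	0.001042	0.020722	0.001042
A[T>C]G	0.000833	0.010162	0.001042	0.179678	0.001042
A[T>C]T	0.000833	0.009242	0.001042	0.038587	0.001042
C[T>C]A	0.000833	0.010095	0.001042	0.025865	0.001042
C[T>C]C	0.000833	0.010785	0.001042	0.083404	0.001042
C[T>C]G	0.000833	0.006431	0.001042	0.042747	0.001042
C[T>C]T	0.000833	0.011501	0.001042	0.044915	0.001042
G[T>C]A	0.000833	0.01054	0.001042	0.050463	0.001042
G[T>C]C	0.000833	0.01267	0.001042	0.108329	0.001042
G[T>C]G	0.000833	0.010647	0.001042	0.012675	0.001042
G[T>C]T	0.000833	0.00738	0.001042	0.023235	0.001042
T[T>C]A	0.000833	0.009028	0.001042	0.011314	0.001042
T[T>C]C	0.000833	0.008735	0.001042	0.106289	0.001042
T[T>C]G	0.000833	0.009537	0.001042	0.036148	0.001042
T[T>C]T	0.000833	0.010055	0.001042	0.048009	0.001042
A[T>G]A	0.000833	0.00976	0.001042	0.001042	0.001042
A[T>G]C	0.000833	0.008796	0.001042	0.001042	0.001042
A[T>G]G	0.000833	0.014365	0.001042	0.001042	0.001042
A[T>G]T	0.000833	0.012428	0.001042	0.001042	0.001042
C[T>G]A	0.000833	0.013141	0.001042	0.001042	0.001042
C[T>G]C	0.000833	0.011542	0.001042	0.001042	0.001042
C[T>G]G	0.000833	0.010076	0.001042	0.001042	0.001042
C[T>G]T	0.000833	0.009127	0.001042	0.001042	0.001042
G[T>G]A	0.000833	0.009439	0.001042	0.001042	0.001042
G[T>G]C	0.000833	0.008235	0.001042	0.001042	0.001042
G[T>G]G	0.000833	0.00973	0.001042	0.001042	0.001042
G[T>G]T	0.000833	0.013607	0.001042	0.001042	0.001042
T[T>G]A	0.000833	0.009268	0.001042	0.001042	0.001042
T[T>G]C	0.000833	0.009956	0.001042	0.001042	0.001042
T[T>G]G	0.000833	0.013544	0.001042	0.001042	0.001042
T[T>G]T	0.000833	0.011194	0.001042	0.001042	0.001042
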