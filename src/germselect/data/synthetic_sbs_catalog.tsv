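channel	SBS1	SBS5	SBS19
A[C>A]A	0.0010869565	0.0052032713	0.013541667
A[C>A]C	0.0010869565	0.0054053818	0.013541667
A[C>A]G	0.0010869565	0.0062696641	0.013541667
A[C>A]T	0.0010869565	0.0045572761	0.013541667
C[C>A]A	0.0010869565	0.003996132	0.013541667
C[C>A]C	0.0010869565	0.0048130518	0.013541667
C[C>A]G	0.0010869565	0.0043061033	0.013541667
C[C>A]T	0.0010869565	0.0068714184	0.013541667
G[C>A]A	0.0010869565	0.0031186322	0.013541667
G[C>A]C	0.0010869565	0.0043730144	0.013541667
G[C>A]G	0.0010869565	0.0033713964	0.013541667
G[C>A]T	0.0010869565	0.005923445	0.013541667
T[C>A]A	0.0010869565	0.0047393155	0.013541667
T[C>A]C	0.0010869565	0.0050246164	0.013541667
T[C>A]G	0.0010869565	0.0068912741	0.013541667
T[C>A]T	0.0010869565	0.0056804059	0.013541667
A[C>G]A	0.0010869565	0.0040945038	0.0010416667
A[C>G]C	0.0010869565	0.0035599584	0.0010416667
A[C>G]G	0.0010869565	0.0031057833	0.0010416667
A[C>G]T	0.0010869565	0.0025607957	0.0010416667
C[C>G]A	0.0010869565	0.0035988903	0.0010416667
C[C>G]C	0.0010869565	0.0033566116	0.0010416667
C[C>G]G	0.0010869565	0.0040919824	0.0010416667
C[C>G]T	0.0010869565	0.0037179893	0.0010416667
G[C>G]A	0.0010869565	0.0026380185	0.0010416667
G[C>G]C	0.0010869565	0.0039786227	0.0010416667
G[C>G]G	0.0010869565	0.0034783558	0.0010416667
G[C>G]T	0.0010869565	0.0023094993	0.0010416667
T[C>G]A	0.0010869565	0.0025724327	0.0010416667
T[C>G]C	0.0010869565	0.0038833034	0.0010416667
T[C>G]G	0.0010869565	0.0021437871	0.0010416667
T[C>G]T	0.0010869565	0.0032143028	0.0010416667
A[C>T]A	0.0010869565	0.015537107	0.0010416667
A[C>T]C	0.0010869565	0.013900261	0.0010416667
A[C>T]G	0.225	0.017617005	0.0010416667
A[C>T]T	0.0010869565	0.018594619	0.0010416667
C[C>T]A	0.0010869565	0.017202887	0.11770833
C[C>T]C	0.0010869565	0.021164395	0.11770833
C[C>T]G	0.225	0.018434863	0.0010416667
C[C>T]T	0.0010869565	0.020227793	0.11770833
G[C>T]A	0.0010869565	0.020955788	0.0010416667
G[C>T]C	0.0010869565	0.011580444	0.0010416667
G[C>T]G	0.225	0.02008728	0.0010416667
G[C>T]T	0.0010869565	0.01028598	0.0010416667
T[C>T]A	0.0010869565	0.014885812	0.11770833
T[C>T]C	0.0010869565	0.016943321	0.11770833
T[C>T]G	0.225	0.012703652	0.0010416667
T[C>T]T	0.0010869565	0.020093833	0.11770833
A[T>A]A	0.0010869565	0.0042824343	0.0010416667
A[T>A]C	0.0010869565	0.0042135879	0.0010416667
A[T>A]G	0.0010869565	0.0053806746	0.0010416667
A[T>A]T	0.0010869565	0.0050701176	0.0010416667
C[T>A]A	0.0010869565	0.0032905224	0.0010416667
C[T>A]C	0.0010869565	0.0057727874	0.0010416667
C[T>A]G	0.0010869565	0.0037517581	0.0010416667
C[T>A]T	0.0010869565	0.0038585305	0.0010416667
G[T>A]A	0.0010869565	0.0032524541	0.0010416667
G[T>A]C	0.0010869565	0.0058181382	0.0010416667
G[T>A]G	0.0010869565	0.0051187488	0.0010416667
G[T>A]T	0.0010869565	0.00448372	0.0010416667
T[T>A]A	0.0010869565	0.00314186	0.0010416667
T[T>A]C	0.0010869565	0.0045710003	0.0010416667
T[T>A]G	0.0010869565	0.0059855373	0.0010416667
T[T>A]T	0.0010869565	0.0043150451	0.0010416667
A[T>C]A	0.0010869565	0.017767986	0.0010416667
A[T>C]C	0.0010869565	0.029867859	0.0010416667
A[T>C]G	0.0010869565	0.025307368	0.0010416667
A[T>C]T	0.0010869565	0.022984023	0.0010416667
C[T>C]A	0.0010869565	0.015992029	0.0010416667
C[T>C]C	0.0010869565	0.027663771	0.0010416667
C[T>C]G	0.0010869565	0.018174309	0.0010416667
C[T>C]T	0.0010869565	0.022706129	0.0010416667
G[T>C]A	0.0010869565	0.020986873	0.0010416667
G[T>C]C	0.0010869565	0.034926352	0.0010416667
G[T>C]G	0.0010869565	0.02356011	0.0010416667
G[T>C]T	0.0010869565	0.02691222	0.0010416667
T[T>C]A	0.0010869565	0.023801311	0.0010416667
T[T>C]C	0.0010869565	0.01794536	0.0010416667
T[T>C]G	0.0010869565	0.02531693	0.0010416667
T[T>C]T	0.0010869565	0.024955837	0.0010416667
A[T>G]A	0.0010869565	0.0089220873	0.0010416667
A[T>G]C	0.0010869565	0.0062804564	0.0010416667
A[T>G]G	0.0010869565	0.0092643161	0.0010416667
A[T>G]T	0.0010869565	0.007785551	0.0010416667
C[T>G]A	0.0010869565	0.012219987	0.0010416667
C[T>G]C	0.0010869565	0.0080135272	0.0010416667
C[T>G]G	0.0010869565	0.010901949	0.0010416667
C[T>G]T	0.0010869565	0.0098871118	0.0010416667
G[T>G]A	0.0010869565	0.010079554	0.0010416667
G[T>G]C	0.0010869565	0.0069776944	0.0010416667
G[T>G]G	0.0010869565	0.011478159	0.0010416667
G[T>G]T	0.0010869565	0.0089251671	0.0010416667
T[T>G]A	0.0010869565	0.0074575776	0.0010416667
T[T>G]C	0.0010869565	0.010685929	0.0010416667
T[T>G]G	0.0010869565	0.0073650053	0.0010416667
T[T>G]T	0.0010869565	0.0095162665	0.0010416667
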