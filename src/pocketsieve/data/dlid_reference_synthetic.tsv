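# Synthetic DLID reference table (generated, not experimental data).
# Drug-like rows emulate mid-size buried apolar pockets; non-drug-like
# rows emulate small shallow polar cavities. Swap in a curated table of
# real pockets via the dlid_reference config key for production use.
volume	buriedness	hydrophobicity	is_druglike
304.8	0.784	0.880	1
258.1	0.916	0.915	1
341.4	0.768	0.680	1
284.3	0.806	0.729	1
128.1	0.794	0.608	1
238.2	0.659	0.721	1
247.9	0.861	0.663	1
347.7	0.907	0.750	1
285.4	0.871	0.514	1
322.7	1.000	0.824	1
566.3	0.660	0.948	1
398.6	0.739	0.462	1
247.9	0.819	0.619	1
397.4	0.862	0.996	1
283.8	0.786	0.721	1
247.6	0.909	0.547	1
290.6	0.834	0.761	1
267.1	0.722	0.755	1
267.4	0.874	0.602	1
282.4	0.777	0.709	1
380.4	0.763	1.000	1
360.7	0.791	0.847	1
628.2	0.739	0.542	1
134.6	0.899	0.833	1
692.4	0.931	0.524	1
221.4	0.722	0.736	1
157.4	0.836	0.612	1
258.2	0.930	0.836	1
257.1	0.880	0.741	1
492.3	0.892	0.501	1
259.0	0.627	0.701	1
170.5	0.849	0.893	1
371.9	0.762	0.796	1
344.7	0.734	0.687	1
274.1	0.776	0.896	1
383.9	0.780	0.520	1
210.4	0.760	0.717	1
352.6	0.787	0.602	1
377.8	0.829	0.725	1
342.6	0.900	0.350	1
261.1	0.903	0.542	1
364.4	0.898	0.775	1
400.0	0.828	1.000	1
456.4	0.673	1.000	1
230.1	0.882	0.513	1
297.1	0.806	0.797	1
456.9	0.781	0.434	1
418.6	0.722	0.594	1
499.0	0.802	0.829	1
247.6	0.775	0.560	1
623.9	0.725	0.980	1
504.0	0.763	0.652	1
395.6	0.844	0.782	1
199.7	0.823	0.526	1
334.2	0.792	0.648	1
235.8	0.805	0.835	1
387.4	0.845	0.735	1
378.0	0.795	0.818	1
498.6	0.977	0.744	1
222.6	0.758	0.958	1
448.2	0.765	0.820	1
397.8	0.860	0.741	1
336.0	0.784	0.737	1
539.0	0.861	0.695	1
552.0	0.668	0.592	1
368.8	0.686	0.571	1
334.1	0.922	0.855	1
373.7	0.901	0.644	1
620.1	0.852	0.669	1
517.1	0.805	0.624	1
441.2	0.932	0.764	1
464.9	0.880	1.000	1
293.4	0.948	0.756	1
270.1	1.000	0.663	1
732.5	0.684	0.444	1
293.6	0.727	0.661	1
290.1	0.857	0.740	1
366.1	0.829	0.646	1
188.5	0.721	0.597	1
403.6	0.824	0.690	1
410.6	0.803	0.805	1
275.9	0.915	0.718	1
528.5	0.784	0.692	1
398.2	0.880	0.771	1
294.6	0.730	0.834	1
386.2	0.898	0.722	1
375.6	0.918	0.815	1
303.7	0.843	0.957	1
770.8	0.723	0.743	1
306.6	0.804	0.664	1
282.9	0.849	0.779	1
508.2	0.795	0.978	1
284.0	0.849	0.737	1
540.2	0.843	0.821	1
405.0	0.825	0.615	1
481.5	0.703	0.865	1
243.9	0.862	0.904	1
238.8	0.814	0.671	1
511.1	0.809	0.704	1
146.2	0.785	0.800	1
711.6	0.706	0.855	1
344.0	0.861	0.671	1
268.5	0.784	0.937	1
311.5	0.796	0.668	1
486.9	0.810	0.586	1
644.8	0.821	0.675	1
383.3	0.875	0.534	1
229.0	0.802	1.000	1
393.3	0.785	0.790	1
987.5	0.876	0.763	1
467.8	0.921	0.861	1
361.3	0.860	0.594	1
246.1	0.883	0.543	1
246.4	0.772	0.714	1
828.6	0.764	0.696	1
287.7	0.858	0.759	1
300.7	0.759	0.644	1
396.0	0.805	0.763	1
458.2	0.671	0.759	1
501.8	0.842	0.506	1
144.8	0.140	0.135	0
112.1	0.372	0.421	0
139.9	0.464	0.167	0
115.2	0.480	0.235	0
216.8	0.441	0.073	0
202.8	0.322	0.285	0
110.3	0.188	0.297	0
55.0	0.159	0.119	0
49.3	0.423	0.244	0
190.0	0.541	0.547	0
245.9	0.333	0.281	0
77.7	0.464	0.198	0
209.6	0.557	0.367	0
47.1	0.104	0.371	0
137.6	0.378	0.303	0
29.7	0.532	0.297	0
325.1	0.607	0.416	0
122.1	0.445	0.367	0
138.4	0.508	0.168	0
149.0	0.611	0.283	0
63.4	0.223	0.309	0
64.3	0.690	0.449	0
70.4	0.504	0.321	0
80.5	0.540	0.194	0
117.8	0.346	0.394	0
116.0	0.379	0.330	0
102.0	0.668	0.243	0
100.3	0.576	0.320	0
96.9	0.318	0.226	0
120.1	0.617	0.046	0
70.9	0.665	0.182	0
132.9	0.361	0.298	0
66.1	0.504	0.268	0
27.3	0.564	0.238	0
193.1	0.444	0.316	0
86.4	0.461	0.573	0
76.5	0.646	0.171	0
38.6	0.519	0.198	0
87.3	0.310	0.476	0
131.7	0.379	0.249	0
99.8	0.403	0.246	0
106.1	0.560	0.363	0
46.0	0.475	0.139	0
95.3	0.545	0.274	0
141.3	0.460	0.157	0
62.4	0.273	0.361	0
112.1	0.712	0.353	0
229.8	0.113	0.096	0
42.1	0.239	0.082	0
47.3	0.750	0.195	0
183.6	0.577	0.191	0
42.1	0.468	0.189	0
125.1	0.374	0.265	0
106.5	0.537	0.301	0
124.2	0.377	0.261	0
52.6	0.367	0.311	0
43.3	0.297	0.154	0
29.5	0.499	0.138	0
91.1	0.290	0.202	0
72.0	0.590	0.345	0
72.1	0.471	0.389	0
99.7	0.585	0.383	0
91.5	0.602	0.060	0
307.2	0.467	0.470	0
203.6	0.524	0.447	0
35.8	0.586	0.359	0
100.0	0.139	0.276	0
82.9	0.427	0.508	0
35.0	0.615	0.282	0
25.5	0.395	0.342	0
101.6	0.650	0.134	0
53.2	0.365	0.348	0
122.9	0.349	0.215	0
63.5	0.643	0.374	0
101.9	0.415	0.264	0
99.2	0.423	0.248	0
67.1	0.479	0.390	0
96.2	0.342	0.380	0
162.4	0.527	0.240	0
135.9	0.437	0.194	0
129.7	0.410	0.223	0
42.3	0.503	0.406	0
52.7	0.458	0.323	0
82.6	0.507	0.407	0
55.6	0.577	0.250	0
14.0	0.378	0.388	0
74.7	0.326	0.213	0
47.8	0.520	0.472	0
96.5	0.505	0.359	0
69.9	0.402	0.097	0
150.2	0.388	0.415	0
57.6	0.546	0.298	0
35.2	0.634	0.187	0
50.2	0.406	0.533	0
68.2	0.477	0.257	0
141.4	0.481	0.398	0
56.8	0.254	0.431	0
51.1	0.256	0.272	0
112.3	0.525	0.342	0
38.8	0.631	0.230	0
46.1	0.396	0.308	0
47.3	0.532	0.234	0
269.9	0.273	0.084	0
164.7	0.605	0.401	0
84.2	0.669	0.336	0
112.2	0.336	0.322	0
117.8	0.537	0.331	0
179.7	0.504	0.439	0
92.8	0.583	0.189	0
53.8	0.335	0.296	0
57.4	0.432	0.298	0
334.8	0.403	0.453	0
251.0	0.548	0.418	0
269.7	0.315	0.132	0
46.1	0.466	0.294	0
70.1	0.304	0.467	0
294.5	0.384	0.417	0
217.7	0.647	0.348	0
430.9	0.431	0.202	0
37.7	0.470	0.288	0
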