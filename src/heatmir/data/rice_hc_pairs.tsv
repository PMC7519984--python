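family	family_direction	gene_id	gene_direction
osa-miR156	up	LOC_Os02g04450	down
osa-miR156	up	LOC_Os03g42320	down
osa-miR156	up	LOC_Os04g46580	down
osa-miR156	up	LOC_Os12g27102	down
osa-miR156	up	LOC_Os03g13460	up_down
osa-miR159	down	LOC_Os01g48850	up
osa-miR159	down	LOC_Os03g02240	up
osa-miR159	down	LOC_Os03g38210	up
osa-miR160	up	LOC_Os01g58730	down
osa-miR160	up	LOC_Os03g14260	down
osa-miR160	up	LOC_Os05g43910	down
osa-miR160	up	LOC_Os06g15680	down
osa-miR160	up	LOC_Os07g37130	down
osa-miR160	up	LOC_Os08g02996	down
osa-miR160	up	LOC_Os08g43570	down
osa-miR160	up	LOC_Os09g29160	down
osa-miR160	up	LOC_Os11g27400	down
osa-miR160	up	LOC_Os11g38140	down
osa-miR164	up	LOC_Os02g44380	down
osa-miR164	up	LOC_Os04g41540	down
osa-miR164	up	LOC_Os06g46270	down
osa-miR164	up	LOC_Os06g49660	down
osa-miR166	up	LOC_Os01g42520	down
osa-miR166	up	LOC_Os02g45380	down
osa-miR166	up	LOC_Os03g14260	down
osa-miR166	up	LOC_Os04g35560	down
osa-miR166	up	LOC_Os04g39864	down
osa-miR166	up	LOC_Os05g48850	down
osa-miR166	up	LOC_Os07g34940	down
osa-miR166	up	LOC_Os10g40100	down
osa-miR166	up	LOC_Os11g46860	down
osa-miR166	up	LOC_Os11g46950	down
osa-miR167	up	LOC_Os01g74610	down
osa-miR167	up	LOC_Os06g03830	down
osa-miR167	up	LOC_Os06g34040	down
osa-miR167	up	LOC_Os08g12760	down
osa-miR168	up_down	LOC_Os01g19990	down
osa-miR168	up_down	LOC_Os01g25300	down
osa-miR168	up_down	LOC_Os02g03700	down
osa-miR168	up_down	LOC_Os02g21520	down
osa-miR168	up_down	LOC_Os04g47870	down
osa-miR168	up_down	LOC_Os08g04460	down
osa-miR168	up_down	LOC_Os01g03270	up
osa-miR168	up_down	LOC_Os01g59550	up
osa-miR168	up_down	LOC_Os02g10800	up
osa-miR168	up_down	LOC_Os02g32200	up
osa-miR168	up_down	LOC_Os06g44034	up
osa-miR168	up_down	LOC_Os07g49000	up
osa-miR168	up_down	LOC_Os08g38610	up
osa-miR168	up_down	LOC_Os10g17790	up
osa-miR169	up_down	LOC_Os01g52864	down
osa-miR169	up_down	LOC_Os02g19970	down
osa-miR169	up_down	LOC_Os02g53620	down
osa-miR169	up_down	LOC_Os06g05390	down
osa-miR169	up_down	LOC_Os10g20990	down
osa-miR169	up_down	LOC_Os11g14570	down
osa-miR169	up_down	LOC_Os01g41650	up
osa-miR169	up_down	LOC_Os01g64980	up
osa-miR169	up_down	LOC_Os02g54200	up
osa-miR169	up_down	LOC_Os03g07880	up
osa-miR169	up_down	LOC_Os03g44540	up
osa-miR169	up_down	LOC_Os03g46770	up
osa-miR169	up_down	LOC_Os04g52550	up
osa-miR169	up_down	LOC_Os08g45000	up
osa-miR169	up_down	LOC_Os12g42400	up
osa-miR172	down	LOC_Os02g56320	up_down
osa-miR172	down	LOC_Os01g52120	up
osa-miR172	down	LOC_Os02g39410	up
osa-miR172	down	LOC_Os03g13370	up
osa-miR172	down	LOC_Os03g50280	up
osa-miR172	down	LOC_Os04g55560	up
osa-miR172	down	LOC_Os06g43220	up
osa-miR172	down	LOC_Os08g39630	up
osa-miR319	up	LOC_Os01g60280	down
osa-miR319	up	LOC_Os08g16660	down
osa-miR319	up	LOC_Os10g38060	down
osa-miR390	up	LOC_Os05g47780	down
osa-miR390	up	LOC_Os07g37130	down
osa-miR390	up	LOC_Os11g09940	down
osa-miR390	up	LOC_Os12g10900	down
osa-miR390	up	LOC_Os08g38410	up_down
osa-miR395	up_down	LOC_Os03g07200	down
osa-miR395	up_down	LOC_Os03g24844	down
osa-miR395	up_down	LOC_Os04g32970	down
osa-miR395	up_down	LOC_Os05g37970	down
osa-miR395	up_down	LOC_Os08g13800	down
osa-miR395	up_down	LOC_Os09g39440	down
osa-miR395	up_down	LOC_Os05g50624	up_down
osa-miR395	up_down	LOC_Os01g07110	up
osa-miR395	up_down	LOC_Os01g55260	up
osa-miR395	up_down	LOC_Os04g31400	up
osa-miR395	up_down	LOC_Os04g55730	up
osa-miR395	up_down	LOC_Os08g07380	up
osa-miR395	up_down	LOC_Os09g25990	up
osa-miR395	up_down	LOC_Os12g01850	up
osa-miR395	up_down	LOC_Os12g18360	up
osa-miR395	up_down	LOC_Os12g27090	up
osa-miR395	up_down	LOC_Os12g38380	up
osa-miR396	down	LOC_Os01g08560	up
osa-miR396	down	LOC_Os02g33230	up
osa-miR396	down	LOC_Os02g47280	up
osa-miR396	down	LOC_Os02g53690	up
osa-miR396	down	LOC_Os06g02560	up
osa-miR396	down	LOC_Os09g34980	up
osa-miR396	down	LOC_Os11g45410	up
osa-miR396	down	LOC_Os12g29980	up
osa-miR399	up	LOC_Os05g10310	down
osa-miR399	up	LOC_Os05g30220	down
osa-miR399	up	LOC_Os08g16580	down
osa-miR399	up	LOC_Os05g45350	up_down
osa-miR408	up	LOC_Os01g01400	down
osa-miR408	up	LOC_Os01g02110	down
osa-miR408	up	LOC_Os02g43660	down
osa-miR408	up	LOC_Os03g15600	down
osa-miR408	up	LOC_Os03g53100	down
osa-miR408	up	LOC_Os05g42010	down
osa-miR408	up	LOC_Os06g11490	down
osa-miR408	up	LOC_Os10g39260	down
osa-miR414	up	LOC_Os01g01960	down
osa-miR414	up	LOC_Os01g13300	down
osa-miR414	up	LOC_Os01g47430	down
osa-miR414	up	LOC_Os01g63980	down
osa-miR414	up	LOC_Os02g03750	down
osa-miR414	up	LOC_Os03g44430	down
osa-miR414	up	LOC_Os03g59760	down
osa-miR414	up	LOC_Os04g30040	down
osa-miR414	up	LOC_Os04g35760	down
osa-miR414	up	LOC_Os04g59494	down
osa-miR414	up	LOC_Os05g51830	down
osa-miR414	up	LOC_Os05g51860	down
osa-miR414	up	LOC_Os08g09270	down
osa-miR414	up	LOC_Os09g36300	down
osa-miR414	up	LOC_Os10g03660	down
osa-miR414	up	LOC_Os11g09150	down
osa-miR414	up	LOC_Os12g01290	down
osa-miR414	up	LOC_Os12g09580	down
osa-miR415	up	LOC_Os02g56550	down
osa-miR415	up	LOC_Os03g61990	down
osa-miR418	down	LOC_Os02g12380	up_down
osa-miR418	down	LOC_Os05g22920	up_down
osa-miR418	down	LOC_Os04g35030	up
osa-miR418	down	LOC_Os04g49270	up
osa-miR419	down	LOC_Os08g20000	up
osa-miR419	down	LOC_Os11g07260	up
osa-miR426	down	LOC_Os06g47210	up
osa-miR435	down	LOC_Os09g09290	up
osa-miR437	down	LOC_Os02g18080	up
osa-miR437	down	LOC_Os02g36140	up
osa-miR437	down	LOC_Os02g42350	up
osa-miR437	down	LOC_Os03g51520	up
osa-miR437	down	LOC_Os11g42220	up
osa-miR439	down	LOC_Os03g14010	up
osa-miR439	down	LOC_Os06g16200	up
osa-miR439	down	LOC_Os07g30950	up
osa-miR440	down	LOC_Os08g20000	up
osa-miR528	up	LOC_Os01g69050	down
osa-miR528	up	LOC_Os10g06760	down
osa-miR528	up	LOC_Os10g24094	down
osa-miR528	up	LOC_Os12g31160	down
osa-miR528	up	LOC_Os10g33104	up_down
osa-miR529	up	LOC_Os02g13020	down
osa-miR529	up	LOC_Os02g39660	down
osa-miR529	up	LOC_Os04g46580	down
osa-miR529	up	LOC_Os07g35140	down
osa-miR529	up	LOC_Os08g35939	down
osa-miR529	up	LOC_Os10g41870	down
osa-miR529	up	LOC_Os12g12130	down
osa-miR529	up	LOC_Os12g38110	up_down
osa-miR530	up	LOC_Os04g51400	down
osa-miR530	up	LOC_Os04g59400	down
osa-miR530	up	LOC_Os11g12290	down
osa-miR530	up	LOC_Os12g32200	down
osa-miR530	up	LOC_Os12g44340	down
osa-miR531	up	LOC_Os05g33630	down
osa-miR531	up	LOC_Os06g01590	down
osa-miR531	up	LOC_Os06g18670	down
osa-miR531	up	LOC_Os06g20320	down
osa-miR531	up	LOC_Os06g46690	down
osa-miR531	up	LOC_Os07g11380	down
osa-miR531	up	LOC_Os10g07229	down
osa-miR531	up	LOC_Os12g04110	down
osa-miR531	up	LOC_Os03g13460	up_down
osa-miR535	up	LOC_Os03g14880	down
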