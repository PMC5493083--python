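name,family,description
X5A,connectivity,Average connectivity index of order 5
HATS4u,GETAWAY,Leverage-weighted autocorrelation of lag 4 / unweighted
Mor10m,3D-MoRSE,Signal 10 / weighted by mass
Mor26p,3D-MoRSE,Signal 26 / weighted by polarizability
Mor09u,3D-MoRSE,Signal 09 / unweighted
Du,WHIM,D total accessibility index / unweighted
BELe1,Burden eigenvalue,Lowest eigenvalue n. 1 of Burden matrix / weighted by atomic Sanderson electronegativities
MATS6e,2D autocorrelation,Moran autocorrelation of lag 6 / weighted by atomic Sanderson electronegativities
Gu,WHIM,G total symmetry index / unweighted
Mor27p,3D-MoRSE,Signal 27 / weighted by polarizability
Mor12m,3D-MoRSE,Signal 12 / weighted by mass
RDF140m,RDF,Radial distribution function 140 / weighted by mass
T(N..O),2D atom pairs,Sum of topological distances between N and O
dipole y,quantum chemical,Electric dipole moment component along the y axis
R3e+,GETAWAY,R maximal autocorrelation of lag 3 / weighted by atomic Sanderson electronegativities
R1e,GETAWAY,R autocorrelation of lag 1 / weighted by atomic Sanderson electronegativities
Mor09m,3D-MoRSE,Signal 09 / weighted by mass
TIE,topological,E-state topological parameter
dipole z,quantum chemical,Electric dipole moment component along the z axis
Mor26e,3D-MoRSE,Signal 26 / weighted by atomic Sanderson electronegativities
ISH,GETAWAY,Standardized information content on the leverage equality
MATS1p,2D autocorrelation,Moran autocorrelation of lag 1 / weighted by atomic polarizabilities
MATS8e,2D autocorrelation,Moran autocorrelation of lag 8 / weighted by atomic Sanderson electronegativities
Ku,WHIM,K global shape index / unweighted
P2m,WHIM,2nd component shape directional WHIM index / weighted by atomic masses
GATS4e,2D autocorrelation,Geary autocorrelation of lag 4 / weighted by atomic Sanderson electronegativities
E3u,WHIM,3rd component accessibility directional WHIM index / unweighted
MATS7e,2D autocorrelation,Moran autocorrelation of lag 7 / weighted by atomic Sanderson electronegativities
G1u,WHIM,1st component symmetry directional WHIM index / unweighted
RDF075m,RDF,Radial distribution function 075 / weighted by mass
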